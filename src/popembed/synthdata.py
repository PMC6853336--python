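"""Synthetic structured-genotype generator.

Provides a no-download test bed with the structural features a
genotype-embedding pipeline is expected to reveal: discrete demes at a
controlled differentiation level (Balding-Nichols model), admixture
gradients ("trails") between two demes, nuclear families with Mendelian
transmission, smooth spatial allele-frequency surfaces, and phenotypes with
group-specific means plus covariate effects.

The Balding-Nichols model draws each deme's allele frequency from
``Beta(p(1-F)/F, (1-p)(1-F)/F)`` around an ancestral frequency
``p ~ Uniform(freq_bounds)``; genotypes are ``Binomial(2, deme frequency)``.
The single parameter ``F`` targets Hudson's F_ST between pairs of demes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_io import MISSING, VARIANT_COLUMNS, GenotypeMatrix

__all__ = [
    "DemeConfig",
    "AdmixTrailConfig",
    "FamilyConfig",
    "SpatialConfig",
    "PhenoConfig",
    "simulate_demes",
    "simulate_admixed",
    "simulate_family",
    "simulate_spatial",
    "simulate_phenotypes",
    "estimate_fst",
    "draw_deme_frequencies",
    "genotypes_from_freqs",
    "write_metadata",
]


# ---------------------------------------------------------------------------
# Configurations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DemeConfig:
    """Isolated randomly-mating demes under the Balding-Nichols model.

    ``fst`` may be a single F for all demes or one value per deme; each must
    lie in [0, 1) (F=1 gives a degenerate Beta and is rejected).
    """

    n_pops: int = 2
    fst: float | tuple[float, ...] = 0.05
    n_per_pop: int | tuple[int, ...] = 100
    L: int = 5000
    freq_bounds: tuple[float, float] = (0.05, 0.95)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_pops < 1:
            raise ValueError("n_pops must be >= 1")
        if self.L < 1:
            raise ValueError("L must be >= 1")
        for f in self.fst_per_pop():
            if not 0.0 <= f < 1.0:
                raise ValueError(f"F={f} outside [0, 1)")
        lo, hi = self.freq_bounds
        if not (0.0 < lo < hi < 1.0):
            raise ValueError("freq_bounds must lie inside (0, 1)")
        for n in self.n_per_pop_list():
            if n < 1:
                raise ValueError("n_per_pop must be >= 1")

    def fst_per_pop(self) -> tuple[float, ...]:
        f = self.fst
        return tuple(f) if np.ndim(f) else (float(f),) * self.n_pops

    def n_per_pop_list(self) -> tuple[int, ...]:
        n = self.n_per_pop
        return tuple(n) if np.ndim(n) else (int(n),) * self.n_pops


@dataclass(frozen=True)
class AdmixTrailConfig:
    """An admixture gradient between two demes: one individual per theta."""

    pop_a: int = 0
    pop_b: int = 1
    n: int = 50
    thetas: tuple[float, ...] | None = None  # default: evenly spaced on [0, 1]

    def theta_grid(self) -> np.ndarray:
        t = (
            np.linspace(0.0, 1.0, self.n)
            if self.thetas is None
            else np.asarray(self.thetas, dtype=float)
        )
        if ((t < 0) | (t > 1)).any():
            raise ValueError("thetas must lie in [0, 1]")
        return t


@dataclass(frozen=True)
class FamilyConfig:
    """A nuclear family: ``founders`` unrelated parents paired into matings
    (consecutive pairs), each mating producing ``offspring_per_mating``
    children with Mendelian transmission."""

    pop: int = 0
    founders: int = 2
    offspring_per_mating: int = 4

    def __post_init__(self) -> None:
        if self.founders < 2 or self.founders % 2:
            raise ValueError("founders must be an even count >= 2")
        if self.offspring_per_mating < 0:
            raise ValueError("offspring_per_mating must be >= 0")


@dataclass(frozen=True)
class SpatialConfig:
    """Samples on a square grid with a smooth allele-frequency surface.

    ``smoothness`` is the correlation length of the Gaussian random field (in
    cells); ``cell_km`` the physical cell size used for coordinates.
    """

    grid: int = 5
    smoothness: float = 2.0
    n_per_cell: int = 10
    cell_km: float = 100.0

    def __post_init__(self) -> None:
        if self.grid < 2:
            raise ValueError("grid must be >= 2 cells per axis")
        if self.smoothness <= 0:
            raise ValueError("smoothness must be > 0")


@dataclass(frozen=True)
class PhenoConfig:
    """Phenotype = group mean + covariate effects + Gaussian noise.

    Covariates are drawn as: age ~ Uniform(40, 70) years, sex ~ Bernoulli(0.5)
    (0=female, 1=male), height ~ Normal(175, 7) cm for males and
    Normal(162, 6) cm for females.  ``covariate_effects`` gives coefficients
    for (age, age^2, height, sex).
    """

    group_means: dict = field(default_factory=dict)
    covariate_effects: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0)
    noise_sd: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")


# ---------------------------------------------------------------------------
# Frequency and genotype draws
# ---------------------------------------------------------------------------

def _default_variants(L: int) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": "1",
            "pos": np.arange(1, L + 1),
            "id": [f"snp{j + 1}" for j in range(L)],
            "ref": "A",
            "alt": "G",
        },
        columns=list(VARIANT_COLUMNS),
    )


def draw_deme_frequencies(
    cfg: DemeConfig, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Ancestral frequencies ``(L,)`` and per-deme frequencies ``(n_pops, L)``."""
    rng = rng or np.random.default_rng(cfg.seed)
    lo, hi = cfg.freq_bounds
    p = rng.uniform(lo, hi, size=cfg.L)
    deme = np.empty((cfg.n_pops, cfg.L))
    for i, F in enumerate(cfg.fst_per_pop()):
        if F == 0.0:
            deme[i] = p
        else:
            a = p * (1.0 - F) / F
            b = (1.0 - p) * (1.0 - F) / F
            deme[i] = rng.beta(a, b)
    return p, deme


def genotypes_from_freqs(freqs: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    """``(n, L)`` diploid genotypes ~ Binomial(2, freqs)."""
    freqs = np.asarray(freqs, dtype=float)
    return rng.binomial(2, freqs[None, :], size=(n, freqs.size)).astype(np.int8)


def simulate_demes(
    cfg: DemeConfig, return_freqs: bool = False
) -> tuple[GenotypeMatrix, pd.DataFrame] | tuple[GenotypeMatrix, pd.DataFrame, np.ndarray]:
    """Simulate genotypes for isolated demes.

    Returns ``(G, table)`` where ``table`` carries ``sample_id`` and the true
    ``pop_label`` (integers 0..n_pops-1).  With ``return_freqs=True`` the
    per-deme frequency matrix is appended, for building trails and families
    on the same frequencies.
    """
    rng = np.random.default_rng(cfg.seed)
    _, deme_freqs = draw_deme_frequencies(cfg, rng)
    blocks, labels = [], []
    for i, n_i in enumerate(cfg.n_per_pop_list()):
        blocks.append(genotypes_from_freqs(deme_freqs[i], n_i, rng))
        labels.extend([i] * n_i)
    calls = np.vstack(blocks)
    samples = [f"S{i:05d}" for i in range(calls.shape[0])]
    G = GenotypeMatrix(calls, _default_variants(cfg.L), samples)
    table = pd.DataFrame({"sample_id": samples, "pop_label": labels})
    if return_freqs:
        return G, table, deme_freqs
    return G, table


def simulate_admixed(
    freqs_a: np.ndarray,
    freqs_b: np.ndarray,
    thetas: np.ndarray,
    seed: int | None = None,
) -> GenotypeMatrix:
    """Admixed individuals: genotype ~ Binomial(2, theta*p_a + (1-theta)*p_b).

    One row per theta; theta=1 reproduces population A, theta=0 population B.
    """
    freqs_a = np.asarray(freqs_a, dtype=float)
    freqs_b = np.asarray(freqs_b, dtype=float)
    if freqs_a.shape != freqs_b.shape:
        raise ValueError("frequency vectors must have equal length")
    thetas = np.asarray(thetas, dtype=float)
    if ((thetas < 0) | (thetas > 1)).any():
        raise ValueError("thetas must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    mix = thetas[:, None] * freqs_a[None, :] + (1.0 - thetas[:, None]) * freqs_b[None, :]
    calls = rng.binomial(2, mix).astype(np.int8)
    samples = [f"ADM{i:04d}" for i in range(len(thetas))]
    return GenotypeMatrix(calls, _default_variants(freqs_a.size), samples)


def _transmit(parent: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    # each parent passes one allele; an allele is alt with probability g/2
    return rng.random(parent.size) < parent / 2.0


#: Three-generation pedigree: grandparents, their two children (one with an
#: unrelated spouse marrying in), and a grandchild.  Entries are
#: ``(id, parent1, parent2)`` with ``None`` parents marking founders.
THREE_GENERATION_PEDIGREE: tuple[tuple[str, str | None, str | None], ...] = (
    ("grandfather", None, None),
    ("grandmother", None, None),
    ("uncle", "grandfather", "grandmother"),
    ("mother", "grandfather", "grandmother"),
    ("father", None, None),
    ("child", "mother", "father"),
)


def nuclear_pedigree(cfg: FamilyConfig) -> tuple[tuple[str, str | None, str | None], ...]:
    """Pedigree for ``cfg``: consecutive founder pairs, each with
    ``offspring_per_mating`` children."""
    rows: list[tuple[str, str | None, str | None]] = [
        (f"F{i}", None, None) for i in range(cfg.founders)
    ]
    for m in range(cfg.founders // 2):
        for c in range(cfg.offspring_per_mating):
            rows.append((f"O{m}_{c}", f"F{2 * m}", f"F{2 * m + 1}"))
    return tuple(rows)


def simulate_family(
    pop_freqs: np.ndarray,
    cfg: FamilyConfig | None = None,
    seed: int | None = None,
    pedigree: tuple[tuple[str, str | None, str | None], ...] | None = None,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Founders drawn from ``pop_freqs``; offspring by Mendelian transmission.

    The family structure is either the nuclear pedigree implied by ``cfg``
    or an explicit ``pedigree`` of ``(id, parent1, parent2)`` rows (``None``
    parents = founder; parents must precede their offspring; offspring have
    exactly two declared parents).  Each parent transmits one of its two
    alleles uniformly at random, so no offspring-parent pair ever carries
    opposite homozygotes.  Returns ``(G, pedigree_table)``.
    """
    rng = np.random.default_rng(seed)
    pop_freqs = np.asarray(pop_freqs, dtype=float)
    if pedigree is None:
        pedigree = nuclear_pedigree(cfg or FamilyConfig())
    genomes: dict[str, np.ndarray] = {}
    rows, ids, roles, p1s, p2s = [], [], [], [], []
    for entry in pedigree:
        if len(entry) != 3:
            raise ValueError(f"pedigree rows must be (id, parent1, parent2): {entry!r}")
        sid, p1, p2 = entry
        if sid in genomes:
            raise ValueError(f"duplicate pedigree id {sid!r}")
        if (p1 is None) != (p2 is None):
            raise ValueError(f"{sid!r} must have either no or exactly two parents")
        if p1 is None:
            g = genotypes_from_freqs(pop_freqs, 1, rng)[0]
            roles.append("founder")
        else:
            if p1 not in genomes or p2 not in genomes:
                raise ValueError(f"parents of {sid!r} must precede it in the pedigree")
            g = (
                _transmit(genomes[p1], rng).astype(np.int8)
                + _transmit(genomes[p2], rng).astype(np.int8)
            )
            roles.append("offspring")
        genomes[sid] = g
        rows.append(g)
        ids.append(sid)
        p1s.append(p1 or "")
        p2s.append(p2 or "")
    calls = np.vstack(rows)
    G = GenotypeMatrix(calls, _default_variants(pop_freqs.size), ids)
    table = pd.DataFrame({"sample_id": ids, "role": roles, "parent1": p1s, "parent2": p2s})
    return G, table


def _grid_field(grid: int, smoothness: float, rng: np.random.Generator) -> np.ndarray:
    """Smooth zero-mean Gaussian field on a grid x grid lattice (flattened)."""
    xs, ys = np.meshgrid(np.arange(grid), np.arange(grid), indexing="ij")
    pts = np.column_stack([xs.ravel(), ys.ravel()]).astype(float)
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
    cov = np.exp(-d2 / (2.0 * smoothness**2)) + 1e-8 * np.eye(grid * grid)
    chol = np.linalg.cholesky(cov)
    return chol @ rng.standard_normal(grid * grid)


def simulate_spatial(
    cfg: SpatialConfig, L: int = 1000, seed: int | None = None
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Spatially structured genotypes on a square grid.

    Each variant's frequency surface is the logistic transform of a smooth
    Gaussian random field added to the logit of an ancestral frequency, so
    nearby cells have correlated frequencies.  Coordinates (cell centres) are
    reported in km as ``northing_km`` / ``easting_km``.
    """
    rng = np.random.default_rng(seed)
    n_cells = cfg.grid * cfg.grid
    p_anc = rng.uniform(0.1, 0.9, size=L)
    logit = np.log(p_anc / (1.0 - p_anc))
    # field scale 0.8 on the logit scale: visible but not saturating gradients
    fields = np.column_stack([_grid_field(cfg.grid, cfg.smoothness, rng) for _ in range(L)])
    freq = 1.0 / (1.0 + np.exp(-(logit[None, :] + 0.8 * fields)))  # (n_cells, L)
    blocks, north, east, cells = [], [], [], []
    for c in range(n_cells):
        blocks.append(genotypes_from_freqs(freq[c], cfg.n_per_cell, rng))
        i, j = divmod(c, cfg.grid)
        north.extend([(i + 0.5) * cfg.cell_km] * cfg.n_per_cell)
        east.extend([(j + 0.5) * cfg.cell_km] * cfg.n_per_cell)
        cells.extend([c] * cfg.n_per_cell)
    calls = np.vstack(blocks)
    samples = [f"SP{i:05d}" for i in range(calls.shape[0])]
    G = GenotypeMatrix(calls, _default_variants(L), samples)
    table = pd.DataFrame(
        {
            "sample_id": samples,
            "cell": cells,
            "northing_km": north,
            "easting_km": east,
        }
    )
    return G, table


def simulate_phenotypes(table: pd.DataFrame, cfg: PhenoConfig) -> pd.DataFrame:
    """Attach covariates and a phenotype to a sample table.

    The group column is ``pop_label`` (or ``group`` if present).  Every group
    in the table must have a mean in ``cfg.group_means``.
    """
    rng = np.random.default_rng(cfg.seed)
    out = table.copy()
    group_col = "group" if "group" in out.columns else "pop_label"
    groups = out[group_col]
    unknown = set(groups.unique()) - set(cfg.group_means)
    if unknown:
        raise ValueError(f"groups without a configured mean: {sorted(map(str, unknown))}")
    n = len(out)
    age = rng.uniform(40.0, 70.0, size=n)
    sex = rng.integers(0, 2, size=n)
    height = np.where(
        sex == 1, rng.normal(175.0, 7.0, size=n), rng.normal(162.0, 6.0, size=n)
    )
    b_age, b_age2, b_height, b_sex = cfg.covariate_effects
    mu = groups.map(cfg.group_means).to_numpy(dtype=float)
    pheno = (
        mu
        + b_age * age
        + b_age2 * age**2
        + b_height * height
        + b_sex * sex
        + rng.normal(0.0, cfg.noise_sd, size=n)
    )
    out["age"] = age
    out["sex"] = sex
    out["height"] = height
    out["phenotype"] = pheno
    return out


# ---------------------------------------------------------------------------
# F_ST estimation (Hudson, ratio of averages)
# ---------------------------------------------------------------------------

def estimate_fst(G: GenotypeMatrix | np.ndarray, labels: np.ndarray) -> float:
    """Hudson F_ST between two populations, ratio-of-averages across variants.

    Per variant, with sample allele frequencies ``p1, p2`` from ``n1, n2``
    sampled alleles: numerator ``(p1-p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)``,
    denominator ``p1(1-p2) + p2(1-p1)``; the estimate is the ratio of the
    across-variant averages.  Missing calls are ignored per variant.
    """
    calls = G.calls if isinstance(G, GenotypeMatrix) else np.asarray(G)
    labels = np.asarray(labels)
    uniq = pd.unique(labels)
    if len(uniq) != 2:
        raise ValueError(f"exactly two populations required, got {len(uniq)}")
    nums, dens = [], []
    for lab in uniq:
        sub = calls[labels == lab]
        if sub.shape[0] < 2:
            raise ValueError("each population needs >= 2 samples")
        ok = sub != MISSING
        n_alleles = 2.0 * ok.sum(axis=0)
        p = np.where(ok, sub, 0).sum(axis=0) / n_alleles
        nums.append(p)
        dens.append(n_alleles)
    p1, p2 = nums
    n1, n2 = dens
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return float(num.mean() / den.mean())


# ---------------------------------------------------------------------------
# Metadata export
# ---------------------------------------------------------------------------

METADATA_COLUMNS = (
    "sample_id",
    "pop_label",
    "theta",
    "northing_km",
    "easting_km",
    "phenotype",
    "age",
    "sex",
    "height",
)


def write_metadata(table: pd.DataFrame, path: str) -> None:
    """Tab-separated metadata with the canonical column set (missing -> NA)."""
    out = pd.DataFrame({c: table.get(c, pd.Series([np.nan] * len(table))) for c in METADATA_COLUMNS})
    out.to_csv(path, sep="\t", index=False, na_rep="NA")
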