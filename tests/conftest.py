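"""Shared fixtures and independent oracles for the test suite."""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest

import popembed as pe
from popembed.genotype_io import VARIANT_COLUMNS


def make_genotypes(calls, chrom="1") -> pe.GenotypeMatrix:
    """Wrap a plain integer array in a GenotypeMatrix with default metadata."""
    calls = np.asarray(calls)
    n, L = calls.shape
    variants = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": np.arange(1, L + 1),
            "id": [f"snp{j}" for j in range(L)],
            "ref": "A",
            "alt": "G",
        },
        columns=list(VARIANT_COLUMNS),
    )
    return pe.GenotypeMatrix(calls, variants, [f"X{i}" for i in range(n)])


# ---------------------------------------------------------------------------
# Independent oracles (deliberately naive implementations)
# ---------------------------------------------------------------------------

def hwe_oracle(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact-rational enumeration of the conditional HWE null.

    P(h) = C(N, h) * C(N - h, (n_minor - h)/2) ... written directly as the
    multinomial times 2^h over the total, all in Fractions; the two-sided p
    sums probabilities <= the observed one with exact comparisons.
    """
    N = n_AA + n_Aa + n_aa
    n_minor = min(2 * n_AA + n_Aa, 2 * n_aa + n_Aa)
    probs = {}
    total = Fraction(0)
    for h in range(n_minor % 2, min(n_minor, 2 * N - n_minor) + 1, 2):
        n_mm = (n_minor - h) // 2
        n_MM = N - n_mm - h
        w = Fraction(
            comb(N, h) * comb(N - h, n_mm) * 2**h
        )
        probs[h] = w
        total += w
    p_obs = probs[n_Aa]
    return float(sum(w for w in probs.values() if w <= p_obs) / total)


def ari_oracle(a, b) -> float:
    """Pair-counting ARI straight from the contingency-table formula."""
    a, b = np.asarray(a), np.asarray(b)
    n = len(a)
    ct = pd.crosstab(a, b).to_numpy()
    sum_comb = sum(comb(int(x), 2) for x in ct.ravel())
    sum_a = sum(comb(int(x), 2) for x in ct.sum(axis=1))
    sum_b = sum(comb(int(x), 2) for x in ct.sum(axis=0))
    expected = sum_a * sum_b / comb(n, 2)
    max_index = (sum_a + sum_b) / 2
    if max_index == expected:
        return 1.0
    return (sum_comb - expected) / (max_index - expected)


def knn_majority_oracle(coords, labels, k) -> float:
    """Brute-force k-NN majority vote with index tie-breaking."""
    coords = np.asarray(coords, dtype=float)
    labels = np.asarray(labels)
    n = len(labels)
    correct = 0
    for i in range(n):
        d = [(np.linalg.norm(coords[i] - coords[j]), j) for j in range(n) if j != i]
        neigh = [j for _, j in sorted(d)[:k]]
        votes = {}
        for j in neigh:
            votes[labels[j]] = votes.get(labels[j], 0) + 1
        best = max(votes.values())
        for j in neigh:  # first tied label in neighbour order
            if votes[labels[j]] == best:
                majority = labels[j]
                break
        correct += majority == labels[i]
    return correct / n


def mutual_knn_oracle(coords, k) -> list[set]:
    """Brute-force mutual-k-NN graph components as a list of index sets."""
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    neigh = []
    for i in range(n):
        d = sorted((np.linalg.norm(coords[i] - coords[j]), j) for j in range(n) if j != i)
        neigh.append({j for _, j in d[:k]})
    adj = {i: {j for j in neigh[i] if i in neigh[j]} for i in range(n)}
    seen, comps = set(), []
    for i in range(n):
        if i in seen:
            continue
        stack, comp = [i], set()
        while stack:
            v = stack.pop()
            if v in comp:
                continue
            comp.add(v)
            stack.extend(adj[v] - comp)
        seen |= comp
        comps.append(comp)
    return comps


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def two_demes():
    """Two demes at F=0.1 (60/pop, L=1000): genotypes, labels, deme freqs."""
    from popembed.synthdata import draw_deme_frequencies, genotypes_from_freqs

    cfg = pe.DemeConfig(n_pops=2, fst=0.1, n_per_pop=60, L=1000, seed=42)
    rng = np.random.default_rng(42)
    _, deme_freqs = draw_deme_frequencies(cfg, rng)
    calls = np.vstack(
        [genotypes_from_freqs(deme_freqs[i], 60, rng) for i in range(2)]
    )
    labels = np.repeat([0, 1], 60)
    return make_genotypes(calls), labels, deme_freqs


@pytest.fixture(scope="session")
def four_deme_scores():
    """PCA(10) scores of a QC'd 4-deme simulation (40/pop, L=1500)."""
    G, table = pe.simulate_demes(
        pe.DemeConfig(n_pops=4, fst=0.1, n_per_pop=40, L=1500, seed=7)
    )
    G2, _ = pe.qc_filter(G)
    model = pe.genotype_pca(G2, 10)
    return model.scores, table["pop_label"].to_numpy()
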