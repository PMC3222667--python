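"""Independent oracles shared between unit and acceptance tests.

Each oracle recomputes a quantity by brute force or enumeration,
independently of the implementation path it is used to check.
"""

from __future__ import annotations

from itertools import product

import numpy as np


# ---------------------------------------------------------------------------
# SNP-calling oracle: direct restatement of the count rules
# ---------------------------------------------------------------------------

def snp_call_oracle(
    counts: dict[str, int], min_depth: int = 4, min_allele_reads: int = 2
) -> tuple[str, str] | None:
    """(major, minor) if the column is a biallelic candidate, else None."""
    acgt = {b: counts.get(b, 0) for b in "ACGT"}
    depth = sum(acgt.values())
    alleles = [b for b in "ACGT" if acgt[b] >= min_allele_reads]
    if len(alleles) != 2 or depth < min_depth:
        return None
    a, b = alleles
    if acgt[a] > acgt[b] or (acgt[a] == acgt[b] and a < b):
        return a, b
    return b, a


def all_columns_up_to_depth(max_depth: int):
    """Every base-count composition over ACGT with total depth <= max_depth."""
    for total in range(0, max_depth + 1):
        for a in range(total + 1):
            for c in range(total - a + 1):
                for g in range(total - a - c + 1):
                    t = total - a - c - g
                    yield {"A": a, "C": c, "G": g, "T": t}


# ---------------------------------------------------------------------------
# Chi-square oracle: expected-count cellwise formula
# ---------------------------------------------------------------------------

def chi2_yates_cellwise(a, b, c, d):
    """Sum over cells of (|O - E| - 0.5)^2 / E with the correction floored.

    Algebraically equivalent to the cross-product formula but computed
    through expected counts, providing an independent route.
    """
    a, b, c, d = (np.asarray(x, dtype=float) for x in (a, b, c, d))
    n = a + b + c + d
    rows = np.stack([a + b, c + d])
    cols = np.stack([a + c, b + d])
    obs = np.stack([a, b, c, d])
    exp = np.stack(
        [
            rows[0] * cols[0] / n,
            rows[0] * cols[1] / n,
            rows[1] * cols[0] / n,
            rows[1] * cols[1] / n,
        ]
    )
    adj = np.maximum(np.abs(obs - exp) - 0.5, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(exp > 0, adj**2 / np.where(exp > 0, exp, 1.0), 0.0)
    return terms.sum(axis=0)


# ---------------------------------------------------------------------------
# ROC AUC oracle: concordant-pair counting
# ---------------------------------------------------------------------------

def auc_pair_counting(scores, labels) -> float:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


# ---------------------------------------------------------------------------
# Codon-table oracle for effect classification
# ---------------------------------------------------------------------------

# Standard genetic code, written out in full so the oracle does not share
# a code path with the implementation.
GENETIC_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

AA_CLASS_ORACLE = {}
for _c, _res in [
    ("nonpolar", "GAVLIPMC"),
    ("polar", "STNQ"),
    ("negative", "DE"),
    ("positive", "KRH"),
    ("aromatic", "FWY"),
]:
    for _a in _res:
        AA_CLASS_ORACLE[_a] = _c


def effect_oracle(codon_ref: str, codon_alt: str) -> str:
    aa1, aa2 = GENETIC_CODE[codon_ref], GENETIC_CODE[codon_alt]
    if aa1 == aa2:
        return "synonymous"
    if aa1 == "*" or aa2 == "*":
        return "nonsyn_nonconservative"
    if AA_CLASS_ORACLE[aa1] == AA_CLASS_ORACLE[aa2]:
        return "nonsyn_conservative"
    return "nonsyn_nonconservative"


def all_single_base_codon_changes():
    """All 576 (codon, mutated codon) pairs differing at one position."""
    for codon in map("".join, product("ACGT", repeat=3)):
        for i in range(3):
            for base in "ACGT":
                if base != codon[i]:
                    yield codon, codon[:i] + base + codon[i + 1 :]


# ---------------------------------------------------------------------------
# Smith-Waterman dynamic-programming oracle (Gotoh affine gaps)
# ---------------------------------------------------------------------------

def smith_waterman_score(
    s1: str,
    s2: str,
    match: float = 2.0,
    mismatch: float = -3.0,
    open_gap: float = -5.0,
    extend_gap: float = -2.0,
) -> float:
    """Full local DP; a gap of length L scores open + (L-1)*extend."""
    n, m = len(s1), len(s2)
    neg = -1e9
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), neg)  # gap in s1 (horizontal)
    F = np.full((n + 1, m + 1), neg)  # gap in s2 (vertical)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] + open_gap, E[i][j - 1] + extend_gap)
            F[i][j] = max(H[i - 1][j] + open_gap, F[i - 1][j] + extend_gap)
            sub = match if s1[i - 1] == s2[j - 1] else mismatch
            H[i][j] = max(0.0, H[i - 1][j - 1] + sub, E[i][j], F[i][j])
            if H[i][j] > best:
                best = H[i][j]
    return best


# ---------------------------------------------------------------------------
# Logistic-likelihood brute maximization (nested grid refinement)
# ---------------------------------------------------------------------------

def logistic_grid_fit(x: np.ndarray, y: np.ndarray, rounds: int = 8):
    """Maximize the two-parameter logistic likelihood by grid refinement."""

    def negll(b0, b1):
        eta = b0 + b1 * x
        return float(np.sum(np.log1p(np.exp(eta))) - np.sum(y * eta))

    lo0, hi0, lo1, hi1 = -10.0, 10.0, -10.0, 10.0
    for _ in range(rounds):
        b0s = np.linspace(lo0, hi0, 41)
        b1s = np.linspace(lo1, hi1, 41)
        vals = [(negll(b0, b1), b0, b1) for b0 in b0s for b1 in b1s]
        _, b0, b1 = min(vals)
        span0 = (hi0 - lo0) / 10
        span1 = (hi1 - lo1) / 10
        lo0, hi0 = b0 - span0, b0 + span0
        lo1, hi1 = b1 - span1, b1 + span1
    return b0, b1
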