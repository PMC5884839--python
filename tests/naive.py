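"""Independent pure-Python reference implementations used as test oracles.

Deliberately naive (string slicing, dict counting, explicit loops) and shared
by several test modules; kept free of any niptkmer internals.
"""

from __future__ import annotations

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def naive_revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def naive_canonical(kmer: str) -> str:
    rc = naive_revcomp(kmer)
    return kmer if kmer <= rc else rc


def naive_enumerate(sequence: str, k: int) -> dict[str, int]:
    """Canonical k-mer counts over ACGT-only windows, case-folded."""
    seq = sequence.upper()
    counts: dict[str, int] = {}
    for i in range(len(seq) - k + 1):
        win = seq[i : i + k]
        if any(b not in "ACGT" for b in win):
            continue
        km = naive_canonical(win)
        counts[km] = counts.get(km, 0) + 1
    return counts


def naive_valid_windows(sequence: str, k: int) -> int:
    seq = sequence.upper()
    return sum(
        1
        for i in range(len(seq) - k + 1)
        if all(b in "ACGT" for b in seq[i : i + k])
    )


def naive_scan_reads(
    reads: list[str], k: int, chrom_sets: dict[str, set[str]]
) -> tuple[dict[str, int], dict[str, int]]:
    """Per-chromosome counts by brute-force substring scan of every read.

    Returns (occurrence counts, distinct counts). ``chrom_sets`` maps
    chromosome name to its set of canonical k-mer strings (assumed disjoint).
    """
    occ = {c: 0 for c in chrom_sets}
    seen: dict[str, set[str]] = {c: set() for c in chrom_sets}
    for read in reads:
        seq = read.upper()
        for i in range(len(seq) - k + 1):
            win = seq[i : i + k]
            if any(b not in "ACGT" for b in win):
                continue
            km = naive_canonical(win)
            for chrom, kset in chrom_sets.items():
                if km in kset:
                    occ[chrom] += 1
                    seen[chrom].add(km)
                    break
    return occ, {c: len(s) for c, s in seen.items()}


def naive_ols(X, y):
    """Explicit normal-equation solve beta = (X^T X)^{-1} X^T y."""
    import numpy as np

    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    return np.linalg.inv(X.T @ X) @ X.T @ y


def naive_poisson_ppf(q: float, lam: float) -> int:
    """Smallest integer x with Poisson CDF(x; lam) >= q, by term summation."""
    import math

    term = math.exp(-lam)
    cdf = term
    x = 0
    while cdf < q:
        x += 1
        term *= lam / x
        cdf += term
        if x > 100000:
            raise RuntimeError("did not converge")
    return x
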