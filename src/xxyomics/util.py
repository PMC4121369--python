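"""Shared helpers: chromosome naming, exact 1-D 2-means, errors."""

from __future__ import annotations

import numpy as np

AUTOSOMES = tuple(str(c) for c in range(1, 23))
VALID_CHROMOSOMES = AUTOSOMES + ("X", "Y")


class XXYomicsError(Exception):
    """Base error for this package."""


class FormatError(XXYomicsError):
    """Malformed input file or table."""


class ConfigError(XXYomicsError):
    """Invalid or contradictory configuration."""


def normalize_chromosome(chrom) -> str:
    """Map 'chr1'/'1'/'chrX'/'x' onto the internal {1..22, X, Y} labels.

    Labels outside the canonical set (haplotype/random contigs) are returned
    stripped of the 'chr' prefix but otherwise unchanged.
    """
    c = str(chrom).strip()
    if c.lower().startswith("chr"):
        c = c[3:]
    if c.upper() in ("X", "Y"):
        return c.upper()
    return c


def two_means_1d(values):
    """Exact 2-means clustering of a 1-D array.

    Enumerates every split point of the sorted values (optimal for k=2 in
    one dimension) so the result is deterministic, unlike iterative k-means.

    Returns (labels, centers) with label 1 = the upper cluster, or None when
    fewer than two distinct values are present.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 2 or np.unique(x).size < 2:
        return None
    order = np.argsort(x, kind="stable")
    xs = x[order]
    csum = np.cumsum(xs)
    csq = np.cumsum(xs * xs)
    total_s, total_q = csum[-1], csq[-1]
    ks = np.arange(1, n)
    s1 = csum[:-1]
    q1 = csq[:-1]
    s2 = total_s - s1
    q2 = total_q - q1
    withinss = (q1 - s1 * s1 / ks) + (q2 - s2 * s2 / (n - ks))
    k = int(ks[np.argmin(withinss)])
    labels = np.zeros(n, dtype=int)
    labels[order[k:]] = 1
    centers = (s1[k - 1] / k, (total_s - s1[k - 1]) / (n - k))
    return labels, centers
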