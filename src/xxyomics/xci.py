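"""X-chromosome-inactivation (XCI) skewing from the AR-locus assay.

Genomic DNA is digested with the methylation-sensitive enzyme HpaII (only
the methylated — inactive-X — allele survives and amplifies) or with MspI
(methylation-insensitive full-digestion control), and the two alleles of
the AR CAG repeat are quantified as electropherogram peak heights. Each
allele's digested peak is normalized by its undigested peak to correct for
amplification efficiency, and the corrected allele-1 share is

    ratio = (h1d/h1u) / (h1d/h1u + h2d/h2u)

with skewing = |ratio - 0.5| x 100 percent (0 = balanced, 50 = complete).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .util import XXYomicsError


class UninformativeAssayError(XXYomicsError):
    pass


@dataclass(frozen=True)
class XCIPeakSet:
    """Averaged peak heights for one sample/tissue (replicates pre-averaged)."""

    sample_id: str
    tissue: str
    h1u: float
    h2u: float
    h1d: float
    h2d: float
    h1m: float = 0.0
    h2m: float = 0.0
    allele1_size: int | None = None
    allele2_size: int | None = None


@dataclass(frozen=True)
class XCIResult:
    sample_id: str
    tissue: str
    ratio: float  # corrected allele-1 share, in [0, 1]
    skewing: float  # percent, in [0, 50]
    mspi_control_pass: bool


def xci_ratio(
    peaks: XCIPeakSet,
    normalize: bool = True,
    mspi_max_frac: float = 0.05,
) -> XCIResult:
    """Corrected XCI ratio and skewing percent for one peak set.

    ``normalize=False`` skips the undigested-peak correction (raw digested
    shares). The MspI control passes iff both MspI peaks are below
    ``mspi_max_frac`` of their undigested peaks (complete digestion).
    """
    if peaks.allele1_size is not None and peaks.allele1_size == peaks.allele2_size:
        raise UninformativeAssayError("homozygous alleles: uninformative locus")
    if peaks.h1u <= 0 or peaks.h2u <= 0:
        raise XXYomicsError("undigested peak heights must be positive")
    if min(peaks.h1d, peaks.h2d, peaks.h1m, peaks.h2m) < 0:
        raise XXYomicsError("peak heights must be non-negative")
    if normalize:
        r1 = peaks.h1d / peaks.h1u
        r2 = peaks.h2d / peaks.h2u
    else:
        r1, r2 = peaks.h1d, peaks.h2d
    if r1 + r2 == 0:
        raise UninformativeAssayError("no digested signal on either allele")
    ratio = r1 / (r1 + r2)
    mspi_pass = (peaks.h1m < mspi_max_frac * peaks.h1u) and (
        peaks.h2m < mspi_max_frac * peaks.h2u
    )
    return XCIResult(
        sample_id=peaks.sample_id,
        tissue=peaks.tissue,
        ratio=float(ratio),
        skewing=float(abs(ratio - 0.5) * 100.0),
        mspi_control_pass=bool(mspi_pass),
    )


def average_replicates(peak_table: pd.DataFrame) -> list[XCIPeakSet]:
    """Average replicate digests (mean peak heights) per sample x tissue."""
    required = {"sample_id", "tissue", "h1u", "h2u", "h1d", "h2d"}
    missing = required - set(peak_table.columns)
    if missing:
        raise XXYomicsError(f"peak table lacks column(s) {sorted(missing)}")
    out = []
    for (sample_id, tissue), group in peak_table.groupby(["sample_id", "tissue"], sort=True):
        kwargs = {}
        for col in ("h1u", "h2u", "h1d", "h2d", "h1m", "h2m"):
            if col in group.columns:
                kwargs[col] = float(group[col].mean())
        for col in ("allele1_size", "allele2_size"):
            if col in group.columns:
                kwargs[col] = int(group[col].iloc[0])
        out.append(XCIPeakSet(sample_id=str(sample_id), tissue=str(tissue), **kwargs))
    return out
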