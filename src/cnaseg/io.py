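"""File formats and the multi-chromosome segmentation driver.

Input is binned genomic data with one floating-point value per fixed-width
bin — either a 4-column bedGraph (chrom, start, end, value; 0-based
half-open) or a headered TSV with chromosome/start/end columns plus one value
column, the dialect exported by standard low-pass WGS preprocessors
(1-based inclusive coordinates are auto-detected from the header dialect and
converted).  Values are used as-is: GC/mappability correction and
normalization are expected upstream.  Non-numeric tokens become missing bins,
which are excluded from the changepoint model and never imputed.

Output is a SEG-style segment table (1-based inclusive coordinates, the
common dialect of genome browsers and CNA tools) plus a bedGraph track of the
posterior changepoint probabilities (0-based half-open).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bcp import BCPHyperparameters, BCPResult, MCMCSettings
from .segmentation import SegmentationConfig, SegmentedProfile, segment

logger = logging.getLogger("cnaseg")

__all__ = [
    "BinnedProfile",
    "read_bins",
    "write_segments",
    "segment_binned",
    "segments_to_frame",
]


@dataclass
class BinnedProfile:
    """Per-bin genomic coordinates and one observed value per bin.

    ``bins`` has columns chromosome / start / end / value with 0-based
    half-open coordinates, sorted and non-overlapping within chromosome;
    missing values are NaN and tracked by :meth:`usable`.
    """

    bins: pd.DataFrame
    source: str = ""

    def __post_init__(self) -> None:
        required = {"chromosome", "start", "end", "value"}
        missing = required - set(self.bins.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        for chrom, grp in self.bins.groupby("chromosome", sort=False):
            starts = grp["start"].to_numpy()
            ends = grp["end"].to_numpy()
            if np.any(ends <= starts):
                raise ValueError(f"{chrom}: bins must have positive width")
            if np.any(np.diff(starts) <= 0) or np.any(starts[1:] < ends[:-1]):
                raise ValueError(f"{chrom}: bins must be sorted and non-overlapping")
            widths = ends - starts
            if widths.size > 1 and np.unique(widths[:-1]).size > 1:
                raise ValueError(f"{chrom}: bins must have constant width")

    @property
    def chromosomes(self) -> list:
        return list(dict.fromkeys(self.bins["chromosome"]))

    @property
    def bin_size(self) -> int:
        widths = (self.bins["end"] - self.bins["start"]).to_numpy()
        return int(np.median(widths))

    def usable(self, chromosome) -> np.ndarray:
        """Boolean mask of non-missing bins for one chromosome."""
        grp = self.bins[self.bins["chromosome"] == chromosome]
        return np.isfinite(grp["value"].to_numpy(dtype=np.float64))

    def values(self, chromosome) -> np.ndarray:
        grp = self.bins[self.bins["chromosome"] == chromosome]
        return grp["value"].to_numpy(dtype=np.float64)


def _looks_one_based(start: np.ndarray, end: np.ndarray) -> bool:
    """Headered-TSV dialect detection: 1-based inclusive coordinates have
    width end - start + 1 and starts congruent to 1 modulo the bin size."""
    if start.size == 0:
        return False
    width_incl = end - start + 1
    if np.unique(width_incl[:-1] if width_incl.size > 1 else width_incl).size != 1:
        return False
    w = int(width_incl[0])
    return bool(np.all(start % w == 1))


def read_bins(path, format: str = "auto") -> BinnedProfile:
    """Read a bedGraph or headered TSV of binned values into a BinnedProfile.

    ``format`` is one of auto / tsv / bedgraph; auto treats a file whose first
    line contains non-numeric column names as a headered TSV.
    """
    path = str(path)
    with open(path) as fh:
        first = fh.readline()
    fields = first.rstrip("\n").split("\t")
    has_header = False
    if format == "tsv":
        has_header = True
    elif format == "auto":
        try:
            float(fields[1])
        except (ValueError, IndexError):
            has_header = True
    elif format != "bedgraph":
        raise ValueError(f"unknown format {format!r}")

    if has_header:
        df = pd.read_csv(path, sep="\t")
        cols = {c.lower(): c for c in df.columns}
        chrom_col = next(
            (cols[k] for k in ("chromosome", "chrom", "chr") if k in cols), None
        )
        if chrom_col is None or "start" not in cols or "end" not in cols:
            raise ValueError(
                f"{path}: expected chromosome/start/end columns, got {list(df.columns)}"
            )
        value_candidates = [
            c
            for c in df.columns
            if c not in (chrom_col, cols["start"], cols["end"])
            and c.lower() not in ("feature", "bin", "name")
        ]
        if len(value_candidates) != 1:
            raise ValueError(
                f"{path}: could not identify a unique value column among "
                f"{value_candidates}"
            )
        out = pd.DataFrame(
            {
                "chromosome": df[chrom_col].astype(str),
                "start": pd.to_numeric(df[cols["start"]]).astype(np.int64),
                "end": pd.to_numeric(df[cols["end"]]).astype(np.int64),
                "value": pd.to_numeric(df[value_candidates[0]], errors="coerce"),
            }
        )
        if _looks_one_based(out["start"].to_numpy(), out["end"].to_numpy()):
            logger.info("%s: detected 1-based inclusive coordinates; converting", path)
            out["start"] = out["start"] - 1
    else:
        out = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=["chromosome", "start", "end", "value"],
            comment="#",
        )
        out["chromosome"] = out["chromosome"].astype(str)
        out["start"] = out["start"].astype(np.int64)
        out["end"] = out["end"].astype(np.int64)
        out["value"] = pd.to_numeric(out["value"], errors="coerce")
    return BinnedProfile(bins=out.reset_index(drop=True), source=path)


def segment_binned(
    profile: BinnedProfile,
    hyper: BCPHyperparameters | None = None,
    settings: MCMCSettings | None = None,
    config: SegmentationConfig | None = None,
) -> dict:
    """Segment each chromosome independently (a changepoint is implicit at
    every chromosome boundary); missing bins are dropped before the model and
    coordinates are reported on the retained bins.

    Returns {chromosome: (BCPResult, SegmentedProfile, retained bin table)}.
    """
    settings = settings or MCMCSettings()
    out = {}
    for k, chrom in enumerate(profile.chromosomes):
        grp = profile.bins[profile.bins["chromosome"] == chrom]
        mask = np.isfinite(grp["value"].to_numpy(dtype=np.float64))
        retained = grp.loc[mask].reset_index(drop=True)
        x = retained["value"].to_numpy(dtype=np.float64)
        if x.size < 2:
            logger.warning("%s: fewer than 2 usable bins, skipped", chrom)
            continue
        chrom_settings = MCMCSettings(
            burnin=settings.burnin,
            m=settings.m,
            seed=(settings.seed + k) % (2**31 - 1),
            thin=settings.thin,
        )
        result, seg_profile = segment(
            x, hyper=hyper, settings=chrom_settings, config=config
        )
        out[chrom] = (result, seg_profile, retained)
    return out


def segments_to_frame(results: dict, sample: str = "sample") -> pd.DataFrame:
    """Flatten segment_binned output to a SEG-style table with genomic
    coordinates (1-based inclusive) mapped back from retained-bin indices."""
    rows = []
    for chrom, (_res, prof, retained) in results.items():
        starts = retained["start"].to_numpy()
        ends = retained["end"].to_numpy()
        for s, e, v in zip(prof.starts, prof.ends, prof.values):
            rows.append(
                {
                    "sample": sample,
                    "chromosome": chrom,
                    "start": int(starts[s]) + 1,
                    "end": int(ends[e]),
                    "num_bins": int(e - s + 1),
                    "segment_value": float(v),
                }
            )
    return pd.DataFrame(rows)


def write_segments(path, results: dict, sample: str = "sample",
                   prob_path=None) -> None:
    """Write the SEG-style TSV (and optionally a bedGraph of posterior
    changepoint probabilities on the retained bins)."""
    frame = segments_to_frame(results, sample=sample)
    with open(path, "w") as fh:
        fh.write("# SEG-style segment table; coordinates are 1-based inclusive\n")
        frame.to_csv(fh, sep="\t", index=False)
    if prob_path is not None:
        with open(prob_path, "w") as fh:
            for chrom, (res, _prof, retained) in results.items():
                starts = retained["start"].to_numpy()
                ends = retained["end"].to_numpy()
                for i, p in enumerate(res.posterior_prob):
                    fh.write(f"{chrom}\t{starts[i]}\t{ends[i]}\t{p:.6g}\n")
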