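"""Domain types and file I/O for BAF/LRR tracks, genome annotation and segments.

Coordinates are 0-based half-open everywhere (BED convention), in files and
in memory.  Chromosome names are normalized to "1".."22", "X" on read.
Missing BAF (bins without an informative SNP) is stored as NaN; such bins
still contribute to the LRR track.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd


class TrackParseError(ValueError):
    """Malformed or out-of-bounds row in an input file."""


# ---------------------------------------------------------------------------
# Genome annotation
# ---------------------------------------------------------------------------

def _normalize_chrom(name: str) -> str:
    name = str(name).strip()
    if name.lower().startswith("chr"):
        name = name[3:]
    return name


@dataclass(frozen=True)
class GenomeAnnotation:
    """Ordered chromosome lengths plus a centromere interval per chromosome.

    The Y chromosome and the mitochondrial genome are excluded: the assay
    covers all autosomes and X only.
    """

    chromosomes: tuple[str, ...]
    lengths: dict[str, int]
    centromeres: dict[str, tuple[int, int]]

    def __post_init__(self) -> None:
        for c in self.chromosomes:
            length = self.lengths[c]
            if length <= 0:
                raise ValueError(f"chromosome {c}: non-positive length {length}")
            cs, ce = self.centromeres[c]
            if not (0 <= cs < ce <= length):
                raise ValueError(
                    f"chromosome {c}: centromere [{cs}, {ce}) outside [0, {length})"
                )
            if c in ("Y", "MT", "M"):
                raise ValueError(f"chromosome {c} is not part of the panel design")

    def order(self, chrom: str) -> int:
        return self.chromosomes.index(chrom)

    @property
    def total_length(self) -> int:
        return sum(self.lengths[c] for c in self.chromosomes)

    def arm_of(self, chrom: str, start: int, end: int) -> str:
        """Return 'p', 'q' or 'pq' for an interval (pq = crosses the centromere)."""
        cs, ce = self.centromeres[chrom]
        if end <= cs:
            return "p"
        if start >= ce:
            return "q"
        return "pq"


def read_genome_annotation(path: str | Path) -> GenomeAnnotation:
    """Read a TSV with columns chrom/length/cen_start/cen_end."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"chrom", "length", "cen_start", "cen_end"}
    missing = required - set(df.columns)
    if missing:
        raise TrackParseError(f"annotation missing columns: {sorted(missing)}")
    chroms, lengths, cens = [], {}, {}
    for _, row in df.iterrows():
        c = _normalize_chrom(row["chrom"])
        chroms.append(c)
        lengths[c] = int(row["length"])
        cens[c] = (int(row["cen_start"]), int(row["cen_end"]))
    return GenomeAnnotation(tuple(chroms), lengths, cens)


def load_grch37() -> GenomeAnnotation:
    """Packaged GRCh37 annotation: chromosomes 1-22 and X with centromeres."""
    ref = resources.files("gsascar.data") / "grch37_annotation.tsv"
    with resources.as_file(ref) as p:
        return read_genome_annotation(p)


# ---------------------------------------------------------------------------
# Bin tracks
# ---------------------------------------------------------------------------

@dataclass
class BinTrack:
    """Per-bin BAF/LRR observations, sorted by (chromosome, start).

    ``bins`` has columns chrom/start/end/baf/lrr.  BAF is a fraction in
    [0, 1] or NaN, LRR a log2 depth ratio (NaN allowed).
    """

    bins: pd.DataFrame
    annotation: GenomeAnnotation

    def __post_init__(self) -> None:
        df = self.bins.reset_index(drop=True)
        order = {c: i for i, c in enumerate(self.annotation.chromosomes)}
        unknown = set(df["chrom"]) - set(order)
        if unknown:
            raise TrackParseError(f"unknown chromosomes: {sorted(unknown)}")
        df = df.sort_values(
            ["chrom", "start"], key=lambda s: s.map(order) if s.name == "chrom" else s
        ).reset_index(drop=True)
        if (df["start"] >= df["end"]).any():
            bad = df.index[df["start"] >= df["end"]][0]
            raise TrackParseError(f"bin {bad}: start >= end")
        for c, grp in df.groupby("chrom", sort=False):
            if (grp["start"].to_numpy()[1:] < grp["end"].to_numpy()[:-1]).any():
                raise TrackParseError(f"overlapping bins on chromosome {c}")
            if grp["end"].max() > self.annotation.lengths[c]:
                raise TrackParseError(f"bin beyond end of chromosome {c}")
        baf = df["baf"].to_numpy(dtype=float)
        ok = np.isnan(baf) | ((baf >= 0.0) & (baf <= 1.0))
        if not ok.all():
            raise TrackParseError(f"BAF outside [0, 1] at bin {int(np.flatnonzero(~ok)[0])}")
        self.bins = df

    def __len__(self) -> int:
        return len(self.bins)

    def subset(self, mask: np.ndarray) -> "BinTrack":
        return BinTrack(self.bins.loc[mask].reset_index(drop=True), self.annotation)

    def chromosome(self, chrom: str) -> pd.DataFrame:
        return self.bins[self.bins["chrom"] == chrom].reset_index(drop=True)


def read_track(path: str | Path, annotation: GenomeAnnotation) -> BinTrack:
    """Read a tab-separated chrom/start/end/baf/lrr file into a BinTrack.

    Rows are validated one by one so errors name the offending line
    (1-based, counting the header as line 1).
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str}, na_values=["NA", "", "."], float_precision="round_trip")
    required = {"chrom", "start", "end", "baf", "lrr"}
    missing = required - set(df.columns)
    if missing:
        raise TrackParseError(f"{path}: missing columns {sorted(missing)}")
    df["chrom"] = df["chrom"].map(_normalize_chrom)
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        if row["chrom"] not in annotation.lengths:
            raise TrackParseError(f"{path}:{line}: unknown chromosome {row['chrom']!r}")
        try:
            start, end = int(row["start"]), int(row["end"])
        except (TypeError, ValueError):
            raise TrackParseError(f"{path}:{line}: non-integer coordinates") from None
        if not (0 <= start < end <= annotation.lengths[row["chrom"]]):
            raise TrackParseError(f"{path}:{line}: coordinates outside chromosome")
        baf = row["baf"]
        if pd.notna(baf) and not (0.0 <= float(baf) <= 1.0):
            raise TrackParseError(f"{path}:{line}: BAF {baf} outside [0, 1]")
    df = df.astype({"start": int, "end": int, "baf": float, "lrr": float})
    return BinTrack(df[["chrom", "start", "end", "baf", "lrr"]], annotation)


def write_track(track: BinTrack, path: str | Path) -> None:
    track.bins.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.17g")


# ---------------------------------------------------------------------------
# Segments
# ---------------------------------------------------------------------------

@dataclass
class Segment:
    """A contiguous genomic interval with summary BAF/LRR statistics.

    ``mean_baf`` is the arithmetic mean of the member bins' mirrored BAF
    (NaN when the segment has no informative SNP bin); ``mean_lrr`` the
    mean LRR of member bins carrying LRR.
    """

    chrom: str
    start: int
    end: int
    n_bins: int
    mean_baf: float
    mean_lrr: float

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class AllelicSegment:
    """A segment with measured and integer allele-specific copy numbers.

    ``cn_star`` is the measured total copy number 2^LRR * 2; (``n_a``,
    ``n_b``) the assigned integer allele copies with n_b >= n_a by the
    mirroring convention; ``cn`` their sum.
    """

    chrom: str
    start: int
    end: int
    n_bins: int
    mean_baf: float
    mean_lrr: float
    cn_star: float
    n_a: int = -1
    n_b: int = -1
    cn: int = -1
    inconsistent: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def minor_cn(self) -> int:
        return min(self.n_a, self.n_b)

    @property
    def is_imbalanced(self) -> bool:
        return self.n_a != self.n_b


SEGMENT_COLUMNS = ["chrom", "start", "end", "n_bins", "mean_baf", "mean_lrr", "cn", "n_a", "n_b"]


def write_segments(segments: Iterable[Segment | AllelicSegment], path: str | Path) -> None:
    """Write segments as BED-like TSV (0-based half-open)."""
    rows = []
    for s in segments:
        rows.append(
            {
                "chrom": s.chrom,
                "start": s.start,
                "end": s.end,
                "n_bins": s.n_bins,
                "mean_baf": s.mean_baf,
                "mean_lrr": s.mean_lrr,
                "cn": getattr(s, "cn", -1),
                "n_a": getattr(s, "n_a", -1),
                "n_b": getattr(s, "n_b", -1),
            }
        )
    df = pd.DataFrame(rows, columns=SEGMENT_COLUMNS)
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.17g")


def read_segments(path: str | Path) -> list[AllelicSegment]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str}, na_values=["NA"], float_precision="round_trip")
    out = []
    for _, r in df.iterrows():
        lrr = float(r["mean_lrr"])
        out.append(
            AllelicSegment(
                chrom=_normalize_chrom(r["chrom"]),
                start=int(r["start"]),
                end=int(r["end"]),
                n_bins=int(r["n_bins"]),
                mean_baf=float(r["mean_baf"]),
                mean_lrr=lrr,
                cn_star=float(2.0 ** lrr * 2.0) if np.isfinite(lrr) else float("nan"),
                cn=int(r["cn"]),
                n_a=int(r["n_a"]),
                n_b=int(r["n_b"]),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

REPORT_FIELDS = ["loh", "tai", "lst", "ploidy", "purity", "k", "hrd_score", "hrd_status", "low_confidence"]


def write_report(report: dict, out_dir: str | Path) -> tuple[Path, Path]:
    """Write the headline scores as JSON and a one-row TSV; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    payload = {k: report.get(k) for k in REPORT_FIELDS}
    json_path = out / "report.json"
    with open(json_path, "w") as fh:
        json.dump(payload, fh, indent=2, default=float)
        fh.write("\n")
    tsv_path = out / "report.tsv"
    pd.DataFrame([payload]).to_csv(tsv_path, sep="\t", index=False)
    return json_path, tsv_path
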