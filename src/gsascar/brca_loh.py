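"""SNP-level majority-vote caller for locus-specific LOH over a gene.

A SNP is informative when the matched control (germline) variant fraction
is consistent with heterozygosity, i.e. between 35% and 65% inclusive.  At
an informative site the tumor variant fraction drifting outside that window
(> 65% or < 35%) marks allelic loss; staying inside marks retention.  A
gene (BRCA1/2 in practice) is called LOH when its LOH sites strictly
outnumber its non-LOH sites.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Sequence

import pandas as pd


class SnpClass(str, Enum):
    LOH = "LOH"
    NON_LOH = "non-LOH"
    UNINFORMATIVE = "uninformative"


class GeneLohVerdict(str, Enum):
    LOH = "LOH"
    NO_LOH = "no-LOH"
    INSUFFICIENT = "insufficient"


@dataclass
class SnpSite:
    position: int
    control_vaf: float
    tumor_vaf: float
    classification: SnpClass = SnpClass.UNINFORMATIVE


@dataclass
class GeneLohCall:
    gene: str
    n_loh: int
    n_non_loh: int
    verdict: GeneLohVerdict


def classify_snp(
    control_vaf: float,
    tumor_vaf: float,
    het_low: float = 0.35,
    het_high: float = 0.65,
) -> SnpClass:
    """Classify one SNP from its control and tumor variant fractions.

    Control in [0.35, 0.65] (inclusive) marks a heterozygous germline site;
    at such a site a tumor fraction strictly outside (0.35, 0.65) marks LOH,
    inside marks non-LOH.  Sites homozygous in the control are uninformative.
    """
    for v in (control_vaf, tumor_vaf):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"variant fraction {v} outside [0, 1]")
    if not (het_low <= control_vaf <= het_high):
        return SnpClass.UNINFORMATIVE
    if tumor_vaf > het_high or tumor_vaf < het_low:
        return SnpClass.LOH
    return SnpClass.NON_LOH


def call_gene_loh(sites: Sequence[SnpSite], gene: str = "") -> GeneLohCall:
    """Majority vote over a gene's informative SNP sites (strict majority)."""
    n_loh = n_non = 0
    for s in sites:
        cls = classify_snp(s.control_vaf, s.tumor_vaf)
        s.classification = cls
        if cls is SnpClass.LOH:
            n_loh += 1
        elif cls is SnpClass.NON_LOH:
            n_non += 1
    if n_loh + n_non == 0:
        verdict = GeneLohVerdict.INSUFFICIENT
    elif n_loh > n_non:
        verdict = GeneLohVerdict.LOH
    else:
        verdict = GeneLohVerdict.NO_LOH
    return GeneLohCall(gene=gene, n_loh=n_loh, n_non_loh=n_non, verdict=verdict)


def read_snp_table(path: str | Path) -> dict[str, list[SnpSite]]:
    """Read a TSV `gene  pos  control_vaf  tumor_vaf` into sites per gene."""
    df = pd.read_csv(path, sep="\t", dtype={"gene": str})
    required = {"gene", "pos", "control_vaf", "tumor_vaf"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    out: dict[str, list[SnpSite]] = {}
    for _, r in df.iterrows():
        out.setdefault(r["gene"], []).append(
            SnpSite(int(r["pos"]), float(r["control_vaf"]), float(r["tumor_vaf"]))
        )
    return out


def call_genes(path: str | Path) -> list[GeneLohCall]:
    return [call_gene_loh(sites, gene) for gene, sites in read_snp_table(path).items()]
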