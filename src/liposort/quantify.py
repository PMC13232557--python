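"""Enrichment arithmetic, qPCR standard curves, and variant counting.

Three quantification routes feed the screening pipeline's readout:

* fold enrichment -- per-genotype fractions before and after sorting and
  their ratio, summarized as mean +/- SD across replicates;
* qPCR -- least-squares standard curve of Cq on log10(concentration)
  (slope -3.32 per decade at 100% amplification efficiency) and its
  inversion to concentrations;
* sequencing -- length filtering of amplicon reads to the 1100-1400 bp
  recovery window, then anchored extraction of the 6-nt variant window
  between exact 12-nt flanks (searched on both strands) and per-variant
  tallying.  Anchored extraction replaces read mapping: it is
  deterministic, needs no reference index, and a substitution inside a
  flank simply discards the read into the QC tally.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from scipy import stats

from .errors import InputError

__all__ = ["VariantTable", "StandardCurve", "MtsExtractor", "fractions_and_fold",
           "summarize_replicates", "fit_standard_curve", "qpcr_concentration",
           "read_fastq", "filter_reads", "count_variants"]


#: Columns of a variant table, in output order.
VARIANT_COLUMNS = ["genotype", "count_pre", "count_post", "frac_pre", "frac_post",
                   "fold_enrichment", "flagged"]

VariantTable = pd.DataFrame  # rows per VARIANT_COLUMNS


@dataclass(frozen=True)
class StandardCurve:
    """Log-linear qPCR calibration: Cq = slope * log10(conc/pM) + intercept."""

    slope: float
    intercept: float
    r_squared: float

    @property
    def efficiency(self) -> float:
        """Amplification efficiency implied by the slope (1.0 = doubling)."""
        return 10.0 ** (-1.0 / self.slope) - 1.0

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"slope": self.slope, "intercept": self.intercept,
                       "r_squared": self.r_squared, "efficiency": self.efficiency},
                      fh, indent=2)


@dataclass(frozen=True)
class MtsExtractor:
    """Anchors for variant-window extraction from amplicon reads."""

    left_flank: str
    right_flank: str
    variant_window: int = 6
    length_window: tuple[int, int] = (1100, 1400)

    def __post_init__(self):
        if not self.left_flank or not self.right_flank:
            raise InputError("flanks must be non-empty")
        if self.variant_window != 6:
            raise InputError("variant window must be 6 nt")


def fractions_and_fold(
    counts_pre: Mapping[str, float],
    counts_post: Mapping[str, float],
) -> VariantTable:
    """Per-genotype fractions and fold enrichment (post fraction / pre fraction).

    Genotypes with zero pre-sort fraction but non-zero post counts are
    flagged rather than assigned an infinite fold.  Fractions are invariant
    to rescaling all counts by a constant.
    """
    genotypes = sorted(set(counts_pre) | set(counts_post))
    pre = np.asarray([counts_pre.get(g, 0) for g in genotypes], dtype=float)
    post = np.asarray([counts_post.get(g, 0) for g in genotypes], dtype=float)
    if (pre < 0).any() or (post < 0).any():
        raise InputError("counts must be non-negative")
    if pre.sum() <= 0 or post.sum() <= 0:
        raise InputError("zero total count in pre or post condition")
    frac_pre = pre / pre.sum()
    frac_post = post / post.sum()
    fold = np.full(len(genotypes), np.nan)
    flagged = np.zeros(len(genotypes), dtype=bool)
    nz = frac_pre > 0
    fold[nz] = frac_post[nz] / frac_pre[nz]
    flagged[~nz & (post > 0)] = True
    return pd.DataFrame(
        {
            "genotype": genotypes,
            "count_pre": pre,
            "count_post": post,
            "frac_pre": frac_pre,
            "frac_post": frac_post,
            "fold_enrichment": fold,
            "flagged": flagged,
        }
    )


def summarize_replicates(tables: Sequence[VariantTable]) -> pd.DataFrame:
    """Mean +/- SD of fractions and fold enrichment across replicate tables.

    Folds are computed per replicate before averaging, matching the usual
    mean +/- SD presentation of replicate enrichment experiments.
    """
    if not tables:
        raise InputError("no replicate tables")
    cat = pd.concat(tables, keys=range(len(tables)), names=["replicate"])
    grp = cat.groupby("genotype")
    out = grp.agg(
        frac_pre_mean=("frac_pre", "mean"),
        frac_pre_sd=("frac_pre", "std"),
        frac_post_mean=("frac_post", "mean"),
        frac_post_sd=("frac_post", "std"),
        fold_mean=("fold_enrichment", "mean"),
        fold_sd=("fold_enrichment", "std"),
    )
    return out.reset_index()


def fit_standard_curve(dilution_series: Sequence[tuple[float, float]]) -> StandardCurve:
    """Least-squares line of Cq on log10(concentration in pM)."""
    conc = np.asarray([c for c, _ in dilution_series], dtype=float)
    cq = np.asarray([q for _, q in dilution_series], dtype=float)
    if (conc <= 0).any():
        raise InputError("concentrations must be positive")
    if len(np.unique(conc)) < 3:
        raise InputError("need at least 3 distinct concentrations")
    x = np.log10(conc)
    res = stats.linregress(x, cq)
    return StandardCurve(slope=float(res.slope), intercept=float(res.intercept),
                         r_squared=float(res.rvalue**2))


def qpcr_concentration(cq: float, curve: StandardCurve) -> float:
    """Invert a standard curve: concentration (pM) at a measured Cq."""
    if curve.slope >= 0:
        raise InputError("invalid standard curve: slope must be negative")
    return 10.0 ** ((cq - curve.intercept) / curve.slope)


def read_fastq(path) -> list:
    """Read a 4-line FASTQ file (.gz transparent)."""
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        try:
            return list(SeqIO.parse(fh, "fastq"))
        except ValueError as exc:
            raise InputError(f"malformed FASTQ {path}: {exc}") from exc


def filter_reads(records: Iterable, length_window: tuple[int, int] = (1100, 1400)) -> list:
    """Keep reads whose length lies in the closed recovery window."""
    lo, hi = length_window
    return [r for r in records if lo <= len(r.seq) <= hi]


def _find_all(haystack: str, needle: str) -> list[int]:
    out, start = [], 0
    while True:
        i = haystack.find(needle, start)
        if i < 0:
            return out
        out.append(i)
        start = i + 1


def count_variants(
    records: Iterable,
    extractor: MtsExtractor,
) -> tuple[dict[str, int], dict[str, int]]:
    """Tally 6-nt variant windows between exact flank anchors.

    Each read is searched for the left flank on the forward strand, then on
    the reverse complement.  Reads are discarded (and tallied in the QC
    stats) when an anchor is missing, occurs more than once, the right
    flank is not found at the expected offset, or the extracted window
    contains an ambiguous base.  The sum of variant counts equals the
    number of successfully extracted reads.
    """
    counts: dict[str, int] = {}
    qc = {"total": 0, "extracted": 0, "missing_anchor": 0,
          "ambiguous_anchor": 0, "bad_right_flank": 0, "ambiguous_window": 0}
    lf, rf, wlen = extractor.left_flank, extractor.right_flank, extractor.variant_window
    for rec in records:
        qc["total"] += 1
        window = None
        reason = "missing_anchor"
        for seq in (str(rec.seq).upper(), str(Seq(str(rec.seq)).reverse_complement()).upper()):
            hits = _find_all(seq, lf)
            if not hits:
                continue
            if len(hits) > 1:
                reason = "ambiguous_anchor"
                break
            start = hits[0] + len(lf)
            if seq[start + wlen : start + wlen + len(rf)] != rf:
                reason = "bad_right_flank"
                break
            cand = seq[start : start + wlen]
            if len(cand) < wlen or any(b not in "ACGT" for b in cand):
                reason = "ambiguous_window"
                break
            window = cand
            break
        if window is None:
            qc[reason] += 1
            continue
        qc["extracted"] += 1
        counts[window] = counts.get(window, 0) + 1
    return counts, qc


def variant_counts_by_name(
    window_counts: Mapping[str, int],
    windows: Mapping[str, str],
) -> dict[str, int]:
    """Map tallied windows onto named variants; unknown windows aggregate as 'other'."""
    rev = {w: name for name, w in windows.items()}
    out = {name: 0 for name in windows}
    other = 0
    for w, c in window_counts.items():
        name = rev.get(w)
        if name is None:
            other += c
        else:
            out[name] += c
    if other:
        out["other"] = other
    return out


def table_to_csv(table: VariantTable, path) -> None:
    table.to_csv(path, index=False)


def table_to_json(table: VariantTable, path) -> None:
    with open(path, "w") as fh:
        json.dump(table.to_dict(orient="records"), fh, indent=2, default=float)
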