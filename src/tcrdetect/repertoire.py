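"""Clonotype-table ingestion, spike-in matching and quality statistics.

Consumes MiXCR-export-style tab-separated clonotype tables (one row per
clonotype with a nucleotide CDR3, a read count and a read fraction), converts
CDR3s to the IMGT junction convention by trimming three nucleotides from each
end, matches spike-in references by exact nucleotide identity per chain, and
computes the accuracy/variability and false-positive statistics used to
assess a sequencing run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ModelParameterError, TableFormatError

__all__ = [
    "ClonotypeRecord",
    "SpikeInReference",
    "FalsePositiveReport",
    "read_clonotype_table",
    "trim_cdr3_to_imgt",
    "match_spikeins",
    "exclude_fully_undetected",
    "dispersion_index",
    "linearity_r2",
    "false_positive_analysis",
]

logger = logging.getLogger(__name__)

#: Column-name candidates for MiXCR-style exports, tried in order.
DEFAULT_COLUMNS = {
    "count": ("cloneCount", "readCount"),
    "fraction": ("cloneFraction", "readFraction"),
    "cdr3_nt": ("nSeqImputedCDR3", "nSeqCDR3"),
}

_VALID_BASES = frozenset("ACGT")

#: Study design tier frequencies (RNA molecules per one million).
STUDY_TIER_FREQS = (1e-6, 3e-6, 1e-5, 5e-5, 3e-4, 1e-3, 3e-3, 1e-2, 5e-2)


@dataclass(frozen=True)
class ClonotypeRecord:
    """One clonotype row: nucleotide CDR3 with its read count and fraction."""

    cdr3_nt: str
    chain: str
    read_count: int
    read_fraction: float = 0.0
    set_id: str = ""
    replicate_id: str = ""


@dataclass(frozen=True)
class SpikeInReference:
    """Ground-truth spike-in clonotype with its designed sample frequency."""

    clone_id: str
    chain: str
    cdr3_nt_imgt: str
    design_freq: float

    def __post_init__(self):
        if not (0.0 < self.design_freq <= 1.0):
            raise ModelParameterError(
                f"design_freq must be in (0, 1], got {self.design_freq}"
            )


def read_clonotype_table(
    path,
    chain: str,
    set_id: str = "",
    replicate_id: str = "",
    columns: dict | None = None,
) -> list[ClonotypeRecord]:
    """Parse a MiXCR-export-style TSV into validated clonotype records.

    Column names are configurable via ``columns`` (keys ``count``,
    ``fraction``, ``cdr3_nt``; values a name or tuple of candidate names).
    Rows whose CDR3 contains non-ACGT characters are dropped with a warning;
    a missing required column or an empty table raises
    :class:`TableFormatError`.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        raise TableFormatError(f"{path}: empty clonotype table") from None
    if df.empty:
        raise TableFormatError(f"{path}: clonotype table has no rows")

    colmap = dict(DEFAULT_COLUMNS)
    if columns:
        for key, val in columns.items():
            colmap[key] = (val,) if isinstance(val, str) else tuple(val)

    def pick(key, required=True):
        for cand in colmap[key]:
            if cand in df.columns:
                return cand
        if required:
            raise TableFormatError(
                f"{path}: missing required column (tried {', '.join(colmap[key])})"
            )
        return None

    count_col = pick("count")
    cdr3_col = pick("cdr3_nt")
    frac_col = pick("fraction", required=False)

    records = []
    for lineno, row in enumerate(df.itertuples(index=False), start=2):
        rowd = row._asdict() if hasattr(row, "_asdict") else dict(zip(df.columns, row))
        cdr3 = str(rowd[cdr3_col]).strip().upper()
        if not cdr3 or not set(cdr3) <= _VALID_BASES:
            logger.warning("%s line %d: non-ACGT CDR3 %r, row skipped", path, lineno, cdr3)
            continue
        try:
            count = int(float(rowd[count_col]))
        except (TypeError, ValueError):
            logger.warning("%s line %d: unparseable count %r, row skipped",
                           path, lineno, rowd[count_col])
            continue
        frac = float(rowd[frac_col]) if frac_col and pd.notna(rowd[frac_col]) else 0.0
        records.append(ClonotypeRecord(cdr3, chain, count, frac, set_id, replicate_id))
    return records


def trim_cdr3_to_imgt(cdr3_nt: str) -> str:
    """Convert a MiXCR CDR3 to the IMGT convention.

    Removes the first and last three nucleotides; the input must be at least
    seven bases long so a non-empty core remains.
    """
    if len(cdr3_nt) < 7:
        raise ModelParameterError(
            f"CDR3 of length {len(cdr3_nt)} cannot be trimmed to IMGT (need >= 7)"
        )
    return cdr3_nt[3:-3]


def _base_replicate(replicate_id: str, merge: bool) -> str:
    if merge and replicate_id and replicate_id[-1] in "ab":
        return replicate_id[:-1]
    return replicate_id


def match_spikeins(
    records,
    reference,
    trim: bool = False,
    merge_duplicate_libraries: bool = True,
) -> pd.DataFrame:
    """Match clonotype records to spike-in references by exact CDR3 identity.

    Records from duplicate libraries (replicate ids ending in ``a``/``b``)
    are merged by summing read counts before the measured frequency is taken
    as matched count over total chain reads in the replicate. Unmatched
    spike-ins appear with count 0 and ``detected = False``.

    Returns a tidy frame with one row per (clone_id, chain, set, replicate).
    """
    refs = [
        r if isinstance(r, SpikeInReference) else SpikeInReference(**r)
        for r in (reference.to_dict("records") if isinstance(reference, pd.DataFrame) else reference)
    ]
    seen = {}
    for r in refs:
        key = (r.chain, r.cdr3_nt_imgt)
        if key in seen:
            raise ModelParameterError(
                f"duplicate reference CDR3 {r.cdr3_nt_imgt} in chain {r.chain} "
                f"(clones {seen[key]} and {r.clone_id}): ambiguous ground truth"
            )
        seen[key] = r.clone_id

    # Aggregate counts per (chain, set, merged replicate, cdr3).
    agg: dict[tuple, int] = {}
    totals: dict[tuple, int] = {}
    for rec in records:
        cdr3 = trim_cdr3_to_imgt(rec.cdr3_nt) if trim else rec.cdr3_nt
        rep = _base_replicate(rec.replicate_id, merge_duplicate_libraries)
        gk = (rec.chain, rec.set_id, rep)
        agg[gk + (cdr3,)] = agg.get(gk + (cdr3,), 0) + rec.read_count
        totals[gk] = totals.get(gk, 0) + rec.read_count

    rows = []
    groups = sorted(totals)
    for chain, set_id, rep in groups:
        total = totals[(chain, set_id, rep)]
        for r in refs:
            if r.chain != chain:
                continue
            count = agg.get((chain, set_id, rep, r.cdr3_nt_imgt), 0)
            rows.append({
                "clone_id": r.clone_id,
                "chain": chain,
                "set_id": set_id,
                "replicate_id": rep,
                "design_freq": r.design_freq,
                "read_count": count,
                "total_reads": total,
                "measured_freq": count / total if total else 0.0,
                "detected": count > 0,
            })
    return pd.DataFrame(rows)


def exclude_fully_undetected(matched: pd.DataFrame, mode: str = "either_chain"):
    """Drop spike-in TCRs undetected everywhere, across all sets/replicates.

    ``mode="either_chain"``: a TCR is excluded when its TRA *or* its TRB CDR3
    has zero reads in every replicate of every set. ``mode="whole_tcr"``:
    excluded only when every chain is fully undetected. Returns
    ``(retained_frame, excluded_clone_ids)``.
    """
    if mode not in ("either_chain", "whole_tcr"):
        raise ModelParameterError(f"unknown exclusion mode {mode!r}")
    chain_detected = matched.groupby(["clone_id", "chain"])["read_count"].max() > 0
    per_clone = chain_detected.groupby("clone_id")
    keep = per_clone.all() if mode == "either_chain" else per_clone.any()
    excluded = sorted(keep.index[~keep])
    retained = matched[~matched["clone_id"].isin(excluded)].reset_index(drop=True)
    return retained, excluded


def dispersion_index(frequencies) -> float:
    """Replicate variability: sample standard deviation divided by mean."""
    vals = np.asarray(frequencies, dtype=float)
    if vals.size < 2:
        raise ModelParameterError("dispersion index needs >= 2 values")
    mean = vals.mean()
    if mean <= 0:
        raise ModelParameterError("dispersion index undefined for mean <= 0")
    return float(vals.std(ddof=1) / mean)


def linearity_r2(truth_freqs, measured_freqs) -> float:
    """Coefficient of determination of measured vs ground-truth frequency.

    Ordinary least squares on (log10 truth, log10 measured), restricted to
    detected points (measured > 0); the number of excluded points is logged.
    """
    truth = np.asarray(truth_freqs, dtype=float)
    measured = np.asarray(measured_freqs, dtype=float)
    if truth.shape != measured.shape:
        raise ModelParameterError("truth and measured arrays must align")
    detected = measured > 0
    n_excluded = int((~detected).sum())
    if n_excluded:
        logger.info("linearity_r2: excluding %d undetected points", n_excluded)
    if detected.sum() < 3:
        raise ModelParameterError("need >= 3 detected pairs for a regression")
    fit = stats.linregress(np.log10(truth[detected]), np.log10(measured[detected]))
    return float(fit.rvalue**2)


@dataclass
class FalsePositiveReport:
    """Per-sequence false-positive table with summary statistics.

    ``table`` has one row per false-positive CDR3 in the control set with its
    control read count, its total count in the comparison sets, its category
    (``elsewhere`` if found in any comparison set, else ``exclusive``) and an
    outlier flag (control count exceeding the largest spike-in count).
    """

    table: pd.DataFrame
    fp_rate_by_chain: dict = field(default_factory=dict)
    fp_rate_by_chain_excl_outliers: dict = field(default_factory=dict)
    removal_fraction_by_cutoff: dict = field(default_factory=dict)
    n_outliers: int = 0

    @property
    def hopping_pairs(self) -> pd.DataFrame:
        """(count elsewhere, count in control) pairs for index-hopping plots."""
        sub = self.table[self.table["category"] == "elsewhere"]
        return sub[["chain", "cdr3_nt", "count_elsewhere", "count_in_control"]]


def false_positive_analysis(
    control_records,
    reference,
    other_set_records,
    cutoffs,
    trim: bool = False,
) -> FalsePositiveReport:
    """Categorize and quantify falsely detected sequences in a control set.

    Every control-set clonotype whose CDR3 is not a spike-in reference is a
    false positive; it is labelled ``elsewhere`` when the same CDR3 occurs in
    any comparison set (the index-hopping signature) and ``exclusive``
    otherwise. For each cutoff ``c`` the removal fraction is the share of
    false-positive sequences with control count <= c (1.0 by convention when
    there are no false positives).
    """
    control_records = list(control_records)
    if not control_records:
        raise ModelParameterError("control set is empty")

    refs = [
        r if isinstance(r, SpikeInReference) else SpikeInReference(**r)
        for r in (reference.to_dict("records") if isinstance(reference, pd.DataFrame) else reference)
    ]
    ref_sets: dict[str, set] = {}
    for r in refs:
        ref_sets.setdefault(r.chain, set()).add(r.cdr3_nt_imgt)

    def aggregate(records):
        out: dict[tuple, int] = {}
        for rec in records:
            cdr3 = trim_cdr3_to_imgt(rec.cdr3_nt) if trim else rec.cdr3_nt
            key = (rec.chain, cdr3)
            out[key] = out.get(key, 0) + rec.read_count
        return out

    control = aggregate(control_records)
    elsewhere = aggregate(other_set_records)

    total_by_chain: dict[str, int] = {}
    spike_max_by_chain: dict[str, int] = {}
    for (chain, cdr3), count in control.items():
        total_by_chain[chain] = total_by_chain.get(chain, 0) + count
        if cdr3 in ref_sets.get(chain, set()):
            spike_max_by_chain[chain] = max(spike_max_by_chain.get(chain, 0), count)

    rows = []
    for (chain, cdr3), count in sorted(control.items()):
        if cdr3 in ref_sets.get(chain, set()):
            continue
        count_elsewhere = elsewhere.get((chain, cdr3), 0)
        rows.append({
            "chain": chain,
            "cdr3_nt": cdr3,
            "count_in_control": count,
            "count_elsewhere": count_elsewhere,
            "category": "elsewhere" if count_elsewhere > 0 else "exclusive",
            "outlier": count > spike_max_by_chain.get(chain, 0),
        })
    table = pd.DataFrame(
        rows,
        columns=["chain", "cdr3_nt", "count_in_control", "count_elsewhere",
                 "category", "outlier"],
    ).astype({"count_in_control": "int64", "count_elsewhere": "int64",
              "outlier": "bool"})

    fp_rate, fp_rate_no_outliers = {}, {}
    for chain, total in total_by_chain.items():
        sub = table[table["chain"] == chain]
        fp_reads = int(sub["count_in_control"].sum())
        fp_rate[chain] = fp_reads / total if total else 0.0
        kept = sub[~sub["outlier"]]
        out_reads = int(sub[sub["outlier"]]["count_in_control"].sum())
        denom = total - out_reads
        fp_rate_no_outliers[chain] = (
            int(kept["count_in_control"].sum()) / denom if denom else 0.0
        )

    removal = {}
    n_fp = len(table)
    for cut in cutoffs:
        if n_fp == 0:
            removal[int(cut)] = 1.0
        else:
            removal[int(cut)] = float((table["count_in_control"] <= cut).mean())

    return FalsePositiveReport(
        table=table,
        fp_rate_by_chain=fp_rate,
        fp_rate_by_chain_excl_outliers=fp_rate_no_outliers,
        removal_fraction_by_cutoff=removal,
        n_outliers=int(table["outlier"].sum()) if n_fp else 0,
    )
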