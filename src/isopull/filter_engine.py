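"""Stringent ion- and protein-level filters, plus bait-driven tuning.

The filter battery (with its standard initial values) is:

===================  =======  =====================================================
parameter            default  a peptide ion / protein passes when ...
===================  =======  =====================================================
q_value_max          0.01     its identification q-value is <= the cutoff
ion_cv_max           0.2      its replicate CV of the normalized L/H ratio is
                              strictly below the cutoff (undefined CV fails)
control_fc           2        none of its control-sample observations deviates
                              from 1 by strictly more than the fold cutoff
data_completeness    1.0      the protein is detected in at least
                              ceil(completeness x n_replicates) replicates
num_peptides_min     2        at least this many distinct passing peptides
seq_coverage_min     40       sequence coverage strictly greater than the cutoff
===================  =======  =====================================================

Boundary conventions follow the parameter descriptions: CV "must be
smaller" and coverage "must be greater" are strict comparisons, the
q-value cutoff is inclusive, the peptide-count minimum is inclusive
("at least"), and the control-fold exclusion is strict. These conventions
are load-bearing for filter tuning: a bait with ion CV 0.28 and coverage
exactly 35% tunes to (ion_cv 0.3, seq_coverage 30) rather than (0.3, 35).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .design_model import SampleType
from .errors import ConfigError, TuningError
from .report_io import ProteinDB, compute_sequence_coverage

log = logging.getLogger(__name__)

CONTROL_SAMPLE_TYPES = (SampleType.WT_WT.value, SampleType.BAIT_BAIT.value)

STRATUM_KEY = ["sample_type", "condition", "fa_level"]


@dataclass(frozen=True)
class FilterParams:
    """Threshold set for the stringent filter battery."""

    control_fc: float = 2.0
    q_value_max: float = 0.01
    ion_cv_max: float = 0.2
    data_completeness: float = 1.0
    seq_coverage_min: float = 40.0
    num_peptides_min: int = 2

    def __post_init__(self):
        if not self.control_fc >= 1:
            raise ConfigError("control_fc must be >= 1")
        if not 0 < self.q_value_max <= 1:
            raise ConfigError("q_value_max must be in (0, 1]")
        if not self.ion_cv_max > 0:
            raise ConfigError("ion_cv_max must be positive")
        if not 0 < self.data_completeness <= 1:
            raise ConfigError("data_completeness must be in (0, 1]")
        if self.num_peptides_min < 1:
            raise ConfigError("num_peptides_min must be >= 1")

    def to_dict(self) -> dict:
        return {
            "control_fc": self.control_fc,
            "q_value_max": self.q_value_max,
            "ion_cv_max": self.ion_cv_max,
            "data_completeness": self.data_completeness,
            "seq_coverage_min": self.seq_coverage_min,
            "num_peptides_min": self.num_peptides_min,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FilterParams":
        return cls(**{k: v for k, v in d.items() if k in cls.__dataclass_fields__})


@dataclass
class FilterAudit:
    """Ordered ledger of filter applications; survivors never increase."""

    entries: list[dict] = field(default_factory=list)

    def record(self, filter_name: str, level: str, tested: int, failed: int) -> None:
        self.entries.append(
            {
                "step": len(self.entries) + 1,
                "filter": filter_name,
                "level": level,
                "tested": int(tested),
                "failed": int(failed),
                "surviving": int(tested - failed),
            }
        )

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.entries,
            columns=["step", "filter", "level", "tested", "failed", "surviving"],
        )


def apply_ion_filters(
    df: pd.DataFrame, params: FilterParams, audit: FilterAudit | None = None
) -> tuple[pd.DataFrame, FilterAudit]:
    """Flag peptide-ion rows passing the q-value and ion-CV filters.

    Expects the ``cv_norm`` column from :func:`isopull.ratio_quant.normalize_runs`.
    The two criteria are conjunctive, so application order cannot change the
    survivor set. Adds a boolean ``ion_pass`` column.
    """
    audit = audit or FilterAudit()
    out = df.copy()
    q_ok = out["q_value"] <= params.q_value_max
    cv_ok = out["cv_norm"] < params.ion_cv_max  # NaN compares False: undefined CV fails
    audit.record("q_value", "ion", len(out), int((~q_ok).sum()))
    audit.record("ion_cv", "ion", int(q_ok.sum()), int((q_ok & ~cv_ok).sum()))
    out["ion_pass"] = q_ok & cv_ok
    return out, audit


def apply_control_fc_filter(
    df: pd.DataFrame, control_fc: float, audit: FilterAudit | None = None
) -> tuple[pd.DataFrame, FilterAudit]:
    """Flag peptides whose control-sample ratios betray unreliable mixing.

    A peptide ion is marked untrusted if any confidently identified
    observation of it in a control sample type (WT/WT or Bait/Bait) has
    ``|log2(ratio_lh_norm)|`` strictly greater than ``log2(control_fc)``.
    The verdict is global per (protein, peptide): one bad control
    observation disqualifies the ion's quantification in the experiment
    sample type everywhere.

    The flag is consumed only by the *experiment* (BAIT_WT) aggregation.
    Control sample types are aggregated without it: measuring control
    enrichment — the evidence the classifier's exclusion logic runs on —
    cannot use a filter that deletes control-enriched observations.

    Adds a boolean ``control_kept`` column.
    """
    audit = audit or FilterAudit()
    out = df.copy()
    log2_cut = math.log2(control_fc)
    in_control = out["sample_type"].isin(CONTROL_SAMPLE_TYPES)
    deviant = (
        in_control
        & out["ion_pass"]
        & (np.abs(np.log2(out["ratio_lh_norm"])) > log2_cut)
    )
    bad_ions = out.loc[deviant, ["protein_id", "peptide_seq"]].drop_duplicates()
    bad_keys = set(map(tuple, bad_ions.itertuples(index=False)))
    keys = list(zip(out["protein_id"], out["peptide_seq"]))
    out["control_kept"] = [k not in bad_keys for k in keys]
    tested = out["ion_pass"] if "ion_pass" in out.columns else pd.Series(True, out.index)
    audit.record(
        "control_fc", "ion", int(tested.sum()),
        int((tested & ~out["control_kept"]).sum()),
    )
    return out, audit


def detected_replicate_counts(surviving: pd.DataFrame) -> pd.DataFrame:
    """Replicates in which each protein retains >= 1 surviving peptide row,
    per (sample_type, condition, fa_level) stratum."""
    return (
        surviving.groupby(["protein_id"] + STRATUM_KEY, sort=False)["replicate"]
        .nunique()
        .rename("n_reps_detected")
        .reset_index()
    )


def protein_filter_table(
    df: pd.DataFrame,
    params: FilterParams,
    protein_db: ProteinDB | None,
    n_replicates: int,
    coverage_column: str | None = None,
) -> pd.DataFrame:
    """Evaluate the protein-level filters per (protein, stratum).

    ``df`` holds peptide rows already flagged by the ion filters; only rows
    with ``ion_pass`` (and, in the experiment sample type, ``control_kept``)
    count as surviving evidence for the completeness and peptide-count
    rules. Sequence coverage is an identification property, so it is
    computed over all confidently identified (q-passing) peptides of the
    protein in the stratum, recomputed from the FASTA database unless
    ``coverage_column`` names a report-provided column to trust instead.

    Returns one row per (protein, stratum) with ``n_reps_detected``,
    ``n_peptides``, ``seq_coverage`` and the boolean verdicts
    ``pass_completeness``, ``pass_num_peptides``, ``pass_coverage``,
    ``protein_pass``.
    """
    surv = df["ion_pass"].copy()
    if "control_kept" in df.columns:
        is_experiment = df["sample_type"] == SampleType.BAIT_WT.value
        surv &= df["control_kept"] | ~is_experiment
    rows = df.loc[surv]

    grouped = rows.groupby(["protein_id"] + STRATUM_KEY, sort=False)
    table = grouped.agg(
        n_reps_detected=("replicate", "nunique"),
        n_peptides=("peptide_seq", "nunique"),
    ).reset_index()

    identified = df.loc[df["q_value"] <= params.q_value_max]
    if coverage_column is not None:
        cov = (
            identified.groupby(["protein_id"] + STRATUM_KEY, sort=False)[coverage_column]
            .max()
            .rename("seq_coverage")
            .reset_index()
        )
        table = table.merge(cov, on=["protein_id"] + STRATUM_KEY, how="left")
    else:
        if protein_db is None:
            raise ConfigError(
                "a FASTA database is required to recompute sequence coverage"
            )
        ident_peps = identified.groupby(["protein_id"] + STRATUM_KEY, sort=False)[
            "peptide_seq"
        ].agg(set)
        covs = []
        for key in table[["protein_id"] + STRATUM_KEY].itertuples(index=False):
            pid = key.protein_id
            if pid not in protein_db:
                raise ConfigError(f"accession {pid!r} absent from the FASTA database")
            peps = ident_peps.get(tuple(key), set())
            covs.append(compute_sequence_coverage(protein_db.sequence(pid), peps))
        table["seq_coverage"] = covs

    need_reps = math.ceil(params.data_completeness * n_replicates)
    table["pass_completeness"] = table["n_reps_detected"] >= need_reps
    table["pass_num_peptides"] = table["n_peptides"] >= params.num_peptides_min
    table["pass_coverage"] = table["seq_coverage"] > params.seq_coverage_min
    table["protein_pass"] = (
        table["pass_completeness"] & table["pass_num_peptides"] & table["pass_coverage"]
    )
    return table


def apply_protein_filters(
    df: pd.DataFrame,
    params: FilterParams,
    protein_db: ProteinDB | None,
    n_replicates: int,
    audit: FilterAudit | None = None,
    coverage_column: str | None = None,
) -> tuple[pd.DataFrame, FilterAudit]:
    """Surviving (protein, stratum) table after the protein-level filters."""
    audit = audit or FilterAudit()
    table = protein_filter_table(df, params, protein_db, n_replicates, coverage_column)
    n = len(table)
    audit.record("data_completeness", "protein", n, int((~table["pass_completeness"]).sum()))
    remain = table["pass_completeness"]
    audit.record(
        "num_peptides", "protein", int(remain.sum()),
        int((remain & ~table["pass_num_peptides"]).sum()),
    )
    remain &= table["pass_num_peptides"]
    audit.record(
        "seq_coverage", "protein", int(remain.sum()),
        int((remain & ~table["pass_coverage"]).sum()),
    )
    return table.loc[table["protein_pass"]].reset_index(drop=True), audit


DEFAULT_CV_GRID = (0.2, 0.25, 0.3)
DEFAULT_SEQCOV_GRID = (40.0, 35.0, 30.0)


def _bait_failure(
    normalized: pd.DataFrame,
    bait_id: str,
    params: FilterParams,
    protein_db: ProteinDB | None,
    n_replicates: int,
) -> str | None:
    """Name of the first filter the bait fails in the experiment stratum, or
    None if the bait survives everything in every BAIT_WT replicate."""
    flagged, _ = apply_ion_filters(normalized, params)
    flagged, _ = apply_control_fc_filter(flagged, params.control_fc)
    table = protein_filter_table(flagged, params, protein_db, n_replicates)
    rows = table[
        (table["protein_id"] == bait_id)
        & (table["sample_type"] == SampleType.BAIT_WT.value)
    ]
    if rows.empty:
        return "ion_filters"  # no surviving bait evidence at all
    for _, r in rows.iterrows():
        if not r["pass_completeness"]:
            return "data_completeness"
        if not r["pass_num_peptides"]:
            return "num_peptides"
        if not r["pass_coverage"]:
            return "seq_coverage"
    return None


def tune_filters(
    normalized: pd.DataFrame,
    bait_id: str,
    params: FilterParams | None = None,
    protein_db: ProteinDB | None = None,
    n_replicates: int = 4,
    cv_grid: Sequence[float] = DEFAULT_CV_GRID,
    seqcov_grid: Sequence[float] = DEFAULT_SEQCOV_GRID,
) -> tuple[FilterParams, pd.DataFrame]:
    """Relax ion-CV and coverage thresholds until the bait survives.

    Walks candidate (seq_coverage_min, ion_cv_max) pairs from most to least
    stringent — coverage descending as the outer loop (coverage stringency
    is surrendered last), CV ascending inside — and returns the first pair
    under which the bait passes every filter in all BAIT_WT replicates,
    together with a trace of every pair tried and the bait's failing filter.

    Raises :class:`TuningError` (with the trace attached) if the bait never
    survives, even at the loosest grid point.
    """
    params = params or FilterParams()
    pairs = [
        (cov, cv)
        for cov in sorted(seqcov_grid, reverse=True)
        for cv in sorted(cv_grid)
    ]
    trace = []
    for cov, cv in pairs:
        trial = replace(params, ion_cv_max=cv, seq_coverage_min=cov)
        failing = _bait_failure(normalized, bait_id, trial, protein_db, n_replicates)
        trace.append(
            {
                "seq_coverage_min": cov,
                "ion_cv_max": cv,
                "bait_survives": failing is None,
                "failing_filter": failing or "",
            }
        )
        if failing is None:
            return trial, pd.DataFrame(trace)
    trace_df = pd.DataFrame(trace)
    err = TuningError(
        f"bait {bait_id!r} fails the filters at every grid point; "
        f"last failure: {trace[-1]['failing_filter']}"
    )
    err.trace = trace_df
    raise err
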