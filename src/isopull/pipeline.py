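"""End-to-end composition of the analysis stages.

``run_pipeline`` takes an ingested peptide report, the sample sheet and a
protein database and drives: ratio inversion and run-median normalization;
the stringent ion-, control- and protein-level filters; protein
aggregation; the moderated one-sample tests with BH correction; and, when
a bait accession is configured, the triple-sample interactor
classification. All intermediate products are returned so that every
filtering decision is auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .design_model import SampleType
from .errors import SchemaError
from .filter_engine import (
    FilterAudit,
    FilterParams,
    apply_control_fc_filter,
    apply_ion_filters,
    apply_protein_filters,
)
from .interactor_classifier import classify_proteins
from .protein_stats import aggregate_proteins_frame, run_differential
from .ratio_quant import normalize_runs
from .report_io import ProteinDB

SAMPLE_FIELDS = ["sample_id", "sample_type", "condition", "fa_level", "replicate"]


@dataclass
class PipelineResult:
    normalized: pd.DataFrame
    flagged: pd.DataFrame
    protein_filter: pd.DataFrame
    protein_quants: pd.DataFrame
    results: pd.DataFrame
    classifications: dict = field(default_factory=dict)
    audit: FilterAudit = field(default_factory=FilterAudit)


def merge_sample_sheet(report: pd.DataFrame, sample_sheet: pd.DataFrame) -> pd.DataFrame:
    """Attach sample-sheet metadata to every report row."""
    missing = [c for c in SAMPLE_FIELDS if c not in sample_sheet.columns]
    if missing:
        raise SchemaError(f"sample sheet lacks columns: {missing}")
    unknown = set(report["sample_id"]) - set(sample_sheet["sample_id"])
    if unknown:
        raise SchemaError(
            f"report references sample_ids absent from the sample sheet: "
            f"{sorted(unknown)[:5]}{'...' if len(unknown) > 5 else ''}"
        )
    return report.merge(sample_sheet[SAMPLE_FIELDS], on="sample_id", how="left")


def run_pipeline(
    report: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    protein_db: ProteinDB | None,
    params: FilterParams | None = None,
    alpha: float = 0.001,
    fc_threshold: float = 2.0,
    bait_id: str | None = None,
    control_alpha: float | None = None,
    coverage_column: str | None = None,
    per_group_fit: bool = False,
) -> PipelineResult:
    params = params or FilterParams()
    audit = FilterAudit()

    merged = merge_sample_sheet(report, sample_sheet)
    n_replicates = int(sample_sheet["replicate"].max())

    normalized = normalize_runs(
        merged, q_value_max=params.q_value_max, ion_cv_max=params.ion_cv_max
    )
    flagged, audit = apply_ion_filters(normalized, params, audit)
    flagged, audit = apply_control_fc_filter(flagged, params.control_fc, audit)

    surviving_proteins, audit = apply_protein_filters(
        flagged, params, protein_db, n_replicates, audit, coverage_column
    )

    # peptide rows feeding aggregation: ion filters everywhere, and the
    # control-consistency flag in the experiment sample type
    surv = flagged["ion_pass"] & (
        flagged["control_kept"]
        | (flagged["sample_type"] != SampleType.BAIT_WT.value)
    )
    keep_keys = surviving_proteins.set_index(
        ["protein_id", "sample_type", "condition", "fa_level"]
    ).index
    rows = flagged.loc[surv]
    row_keys = pd.MultiIndex.from_frame(
        rows[["protein_id", "sample_type", "condition", "fa_level"]]
    )
    rows = rows.loc[row_keys.isin(keep_keys)]

    quants = aggregate_proteins_frame(rows)
    quants = quants.merge(
        surviving_proteins[
            ["protein_id", "sample_type", "condition", "fa_level", "seq_coverage"]
        ],
        on=["protein_id", "sample_type", "condition", "fa_level"],
        how="left",
    )

    results = run_differential(
        quants, alpha=alpha, fc_threshold=fc_threshold, per_group_fit=per_group_fit
    )

    classifications = {}
    if bait_id is not None and not results.empty:
        for (cond, fa), chunk in results.groupby(["condition", "fa_level"], sort=False):
            classifications[(cond, fa)] = classify_proteins(
                chunk, bait_id, alpha=alpha, fc_threshold=fc_threshold,
                control_alpha=control_alpha,
            )

    return PipelineResult(
        normalized=normalized,
        flagged=flagged,
        protein_filter=surviving_proteins,
        protein_quants=quants,
        results=results,
        classifications=classifications,
        audit=audit,
    )
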