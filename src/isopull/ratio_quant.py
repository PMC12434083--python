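"""Ratio inversion, ion-level dispersion, and run-median normalization.

The search engine exports heavy/light ratios; these are inverted so the
light (14N) channel — the channel carrying the bait strain in the
experiment mix — sits in the numerator. Because light and heavy pellets
are mixed 1:1 before purification, the background peptide population of
every run should sit at L/H = 1; each run's residual mixing error is
removed by dividing every peptide ratio by the run's median L/H over
QC-passing peptides, which centers the background distribution on 1 by
construction.

The QC set feeding the median applies the q-value filter first, then an
ion-CV screen, then takes the median of survivors. The CV screen cannot
run on raw ratios: across replicate runs the raw L/H of every ion carries
each run's mixing error, so a raw-ratio CV preferentially selects ions
whose noise happens to cancel the mixing differences, and the factor
derived from that selection is biased toward 1. Each run is therefore
first centered by a provisional median over q-passing peptides alone; the
CV screen runs on the provisionally centered ratios (where the mixing
error has dropped out), and the final factor is the provisional factor
times the median of centered ratios over the full QC set — which also
pins the post-normalization QC median at exactly 1.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import DomainError, NormalizationError

#: Replication axis for ion CVs: one peptide ion observed across the
#: biological replicates of one sample type within one condition/FA stratum.
ION_GROUP_KEY = ["protein_id", "peptide_seq", "sample_type", "condition", "fa_level"]


def invert_ratio(ratio_hl: float) -> float:
    """L/H ratio from an exported H/L ratio."""
    if not np.isfinite(ratio_hl) or ratio_hl <= 0:
        raise DomainError(f"ratio_hl must be finite and positive, got {ratio_hl}")
    return 1.0 / ratio_hl


def ion_cv(values) -> float:
    """Coefficient of variation (sample sd / mean) of replicate ratios.

    Defined for two or more observations; returns NaN otherwise (an
    undefined CV counts as a filter failure downstream).
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        return float("nan")
    return float(arr.std(ddof=1) / arr.mean())


def normalization_factor(ratios_lh) -> float:
    """Median L/H over a run's QC-passing peptides.

    Even-count medians are the mean of the two central order statistics.
    """
    arr = np.asarray(list(ratios_lh), dtype=float)
    if arr.size == 0:
        raise NormalizationError("no QC-passing peptides to derive a factor from")
    return float(np.median(arr))


def _group_cv(df: pd.DataFrame, value_col: str, mask: pd.Series) -> pd.Series:
    """Per-row CV of ``value_col`` over the rows of the same ion group that
    satisfy ``mask``; NaN where fewer than two such observations exist."""
    sub = df.loc[mask, ION_GROUP_KEY + [value_col]]
    stats = sub.groupby(ION_GROUP_KEY, sort=False)[value_col].agg(["mean", "std", "count"])
    cv = (stats["std"] / stats["mean"]).where(stats["count"] >= 2)
    cv.name = "cv"
    joined = df[ION_GROUP_KEY].merge(
        cv.reset_index(), on=ION_GROUP_KEY, how="left", sort=False
    )
    return joined["cv"].set_axis(df.index)


def normalize_runs(
    df: pd.DataFrame,
    q_value_max: float = 0.01,
    ion_cv_max: float = 0.2,
) -> pd.DataFrame:
    """Invert and median-normalize every run of a merged peptide table.

    ``df`` must carry the measurement fields plus the sample-sheet fields
    (``sample_type``, ``condition``, ``fa_level``, ``replicate``).

    Adds columns:

    ``ratio_lh``       inverted ratio, light over heavy;
    ``cv_prenorm``     ion CV across replicates of the provisionally
                       centered ratio (over q-passing observations);
    ``qc_pass``        q-value <= ``q_value_max`` and ``cv_prenorm``
                       strictly below ``ion_cv_max`` (undefined CV fails);
    ``norm_factor``    the run's final normalization factor: provisional
                       q-median times the QC-set median of centered ratios;
    ``ratio_lh_norm``  ``ratio_lh / norm_factor`` for *every* row — QC
                       status is carried, not deleted, so downstream
                       filters stay auditable;
    ``cv_norm``        ion CV recomputed on normalized ratios (the value
                       the stringent ion filter consumes).

    Raises :class:`NormalizationError` naming the first run left without
    any QC-passing peptide.
    """
    bad = ~np.isfinite(df["ratio_hl"]) | (df["ratio_hl"] <= 0)
    if bad.any():
        raise DomainError(
            f"{int(bad.sum())} rows have non-finite or non-positive ratio_hl; "
            "reject them at ingest"
        )
    out = df.copy()
    out["ratio_lh"] = 1.0 / out["ratio_hl"]
    q_ok = out["q_value"] <= q_value_max

    def _run_medians(values: pd.Series, mask: pd.Series, stage: str) -> pd.Series:
        med = out.loc[mask].assign(_v=values[mask]).groupby("sample_id", sort=False)["_v"].median()
        missing = set(out["sample_id"].unique()) - set(med.index)
        if missing:
            raise NormalizationError(
                f"run {sorted(missing)[0]!r} has no {stage} peptides; cannot normalize"
            )
        return out["sample_id"].map(med)

    prelim = _run_medians(out["ratio_lh"], q_ok, "q-passing")
    centered = out["ratio_lh"] / prelim

    out["cv_prenorm"] = _group_cv(out.assign(_c=centered), "_c", q_ok)
    out["qc_pass"] = q_ok & (out["cv_prenorm"] < ion_cv_max)

    residual = _run_medians(centered, out["qc_pass"], "QC-passing")
    out["norm_factor"] = prelim * residual
    out["ratio_lh_norm"] = out["ratio_lh"] / out["norm_factor"]

    out["cv_norm"] = _group_cv(out, "ratio_lh_norm", q_ok)
    return out
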