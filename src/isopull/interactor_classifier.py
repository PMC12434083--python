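"""Triple-sample exclusion logic: from per-sample-type results to a
classified interactor list.

Only proteins that bind nonspecifically to the capture resin should show
up enriched in the WT/WT control, and only labeling/tag artifacts in the
Bait/Bait control; genuine partners of the bait enrich the light channel
of the Bait/WT experiment alone. The decision table, applied to the union
of proteins seen in any of the three result tables, is therefore:

1. the configured bait accession -> ``bait``;
2. significantly enriched in WT/WT -> ``excluded_wt_control`` ("red");
3. significantly enriched in Bait/Bait -> ``excluded_bait_control`` ("yellow");
4. significantly enriched in Bait/WT -> ``candidate``;
5. otherwise -> ``not_significant``.

"Significantly enriched in a control" reuses the experiment's own rule
(BH-adjusted p <= alpha and fold >= fc_threshold), optionally with a
separate ``control_alpha``. Mere detection in a control at a ratio near 1
— the signature of nonspecific binders such as biotinylated carboxylases —
never triggers exclusion.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .design_model import SampleType
from .errors import DomainError
from .protein_stats import bh_adjust, fit_hyperparameters, D0_CAP
from scipy.stats import t as t_dist

log = logging.getLogger(__name__)

STATUS_BAIT = "bait"
STATUS_CANDIDATE = "candidate"
STATUS_EXCLUDED_WT = "excluded_wt_control"
STATUS_EXCLUDED_BAIT = "excluded_bait_control"
STATUS_NOT_SIGNIFICANT = "not_significant"

CLASSIFICATION_COLUMNS = [
    "protein_id", "status", "reason",
    "bait_wt_fold", "bait_wt_adj_p",
    "wt_wt_fold", "wt_wt_adj_p",
    "bait_bait_fold", "bait_bait_adj_p",
]


def _lookup(results: pd.DataFrame | None, sample_type: str) -> pd.DataFrame:
    if results is None or results.empty:
        return pd.DataFrame(columns=["protein_id", "enrichment_fold", "adj_p", "significant"])
    sub = results[results["sample_type"] == sample_type]
    return sub.set_index("protein_id")[["enrichment_fold", "adj_p", "significant"]]


def classify_proteins(
    results: pd.DataFrame,
    bait_id: str,
    alpha: float = 0.001,
    fc_threshold: float = 2.0,
    control_alpha: float | None = None,
) -> pd.DataFrame:
    """Classify every protein of one (condition, fa_level) analysis.

    ``results`` is the moderated-test table holding up to three sample
    types; absence of a protein from a sample type's table is treated as
    non-enriched there. Logs a warning if the bait itself is missing from
    the Bait/WT results (it was lost to filtering — consider filter
    tuning).
    """
    exp = _lookup(results, SampleType.BAIT_WT.value)
    wt = _lookup(results, SampleType.WT_WT.value)
    bb = _lookup(results, SampleType.BAIT_BAIT.value)

    if control_alpha is None:
        control_alpha = alpha

    def enriched(tbl: pd.DataFrame, pid: str, a: float) -> bool:
        if pid not in tbl.index:
            return False
        row = tbl.loc[pid]
        return bool(row["adj_p"] <= a and row["enrichment_fold"] >= fc_threshold)

    universe = sorted(set(exp.index) | set(wt.index) | set(bb.index))
    if bait_id not in exp.index:
        log.warning(
            "bait %r not present in the Bait/WT results: it was lost by "
            "filtering; consider tune_filters", bait_id,
        )

    records = []
    for pid in universe:
        if pid == bait_id:
            status, reason = STATUS_BAIT, "configured bait accession"
        elif enriched(wt, pid, control_alpha):
            status = STATUS_EXCLUDED_WT
            reason = "significantly enriched in the WT/WT control (nonspecific)"
        elif enriched(bb, pid, control_alpha):
            status = STATUS_EXCLUDED_BAIT
            reason = "significantly enriched in the Bait/Bait control (tag artifact)"
        elif enriched(exp, pid, alpha):
            status = STATUS_CANDIDATE
            reason = "enriched in Bait/WT only"
        else:
            status, reason = STATUS_NOT_SIGNIFICANT, "no significant enrichment"

        def val(tbl, col):
            return float(tbl.loc[pid, col]) if pid in tbl.index else np.nan

        records.append(
            {
                "protein_id": pid,
                "status": status,
                "reason": reason,
                "bait_wt_fold": val(exp, "enrichment_fold"),
                "bait_wt_adj_p": val(exp, "adj_p"),
                "wt_wt_fold": val(wt, "enrichment_fold"),
                "wt_wt_adj_p": val(wt, "adj_p"),
                "bait_bait_fold": val(bb, "enrichment_fold"),
                "bait_bait_adj_p": val(bb, "adj_p"),
            }
        )
    return pd.DataFrame(records, columns=CLASSIFICATION_COLUMNS)


def compare_conditions(
    results_a: pd.DataFrame,
    results_b: pd.DataFrame,
    alpha: float = 0.01,
    d0_cap: float = D0_CAP,
) -> pd.DataFrame:
    """Moderated two-group contrast of Bait/WT enrichment between conditions.

    Inputs are moderated-test result tables (one condition each) restricted
    to — or at least containing — the Bait/WT sample type; they must carry
    ``mean_log2``, ``s2_g`` and ``n_reps``. The contrast is
    ``mean_log2(A) - mean_log2(B)`` with a pooled moderated variance

        s2_post = (d0*s0^2 + dA*s2A + dB*s2B) / (d0 + dA + dB)

    where (d0, s0^2) is refit on the combined variance set, and a t
    statistic on ``d0 + dA + dB`` degrees of freedom. BH is applied within
    the contrast vector. Proteins present in only one condition are
    reported with ``in_both = False`` and no contrast.
    """
    def _prep(res: pd.DataFrame) -> pd.DataFrame:
        sub = res[res["sample_type"] == SampleType.BAIT_WT.value]
        if sub.empty:
            raise DomainError("no BAIT_WT rows in a condition's result table")
        return sub.set_index("protein_id")[["mean_log2", "s2_g", "n_reps"]]

    a, b = _prep(results_a), _prep(results_b)
    both = sorted(set(a.index) & set(b.index))
    only = sorted(set(a.index) ^ set(b.index))

    s2 = np.concatenate([a["s2_g"].to_numpy(), b["s2_g"].to_numpy()])
    dg = np.concatenate([a["n_reps"].to_numpy() - 1, b["n_reps"].to_numpy() - 1]).astype(float)
    try:
        d0, s0_2 = fit_hyperparameters(s2, dg, d0_cap)
    except Exception:
        d0, s0_2 = d0_cap, 0.0

    rows = []
    for pid in both:
        ma, sa, na = a.loc[pid]
        mb, sb, nb = b.loc[pid]
        da, db = na - 1, nb - 1
        s2_post = (d0 * s0_2 + da * sa + db * sb) / (d0 + da + db)
        contrast = ma - mb
        df = d0 + da + db
        if s2_post > 0:
            t = contrast / np.sqrt(s2_post * (1.0 / na + 1.0 / nb))
            p = 2.0 * t_dist.sf(abs(t), df)
        elif contrast == 0:
            t, p = 0.0, 1.0
        else:
            t, p = float(np.sign(contrast)) * np.inf, 0.0
        rows.append(
            {
                "protein_id": pid, "in_both": True,
                "mean_log2_a": float(ma), "mean_log2_b": float(mb),
                "contrast": float(contrast), "t_mod": float(t),
                "df": float(df), "p": float(p),
            }
        )
    res = pd.DataFrame(
        rows,
        columns=["protein_id", "in_both", "mean_log2_a", "mean_log2_b",
                 "contrast", "t_mod", "df", "p"],
    )
    if not res.empty:
        res["adj_p"] = bh_adjust(res["p"].to_numpy())
        res["significant"] = res["adj_p"] <= alpha
    else:
        res["adj_p"] = []
        res["significant"] = []
    if only:
        flagged = pd.DataFrame(
            {
                "protein_id": only, "in_both": False,
                "mean_log2_a": np.nan, "mean_log2_b": np.nan,
                "contrast": np.nan, "t_mod": np.nan, "df": np.nan,
                "p": np.nan, "adj_p": np.nan, "significant": False,
            }
        )
        res = pd.concat([res, flagged], ignore_index=True)
    return res.sort_values("protein_id").reset_index(drop=True)
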