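"""Triple-sample mixing design for ratio-based pull-down experiments.

Each biological replicate contributes three mixed samples built from a
light (14N) and a heavy (15N) cell pellet:

* ``WT_WT``     — untagged/untagged mix; nonspecific-binding control.
* ``BAIT_WT``   — tagged light vs. untagged heavy; the experiment, where
  the bait and everything crosslinked to it enriches the light channel.
* ``BAIT_BAIT`` — tagged/tagged mix; labeling and tag control where every
  protein is expected near a light/heavy ratio of 1.

The full factorial crosses these three sample types with the growth
conditions and crosslinker (formaldehyde) levels under study.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .errors import InvalidDesignError


class SampleType(str, enum.Enum):
    WT_WT = "WT_WT"
    BAIT_WT = "BAIT_WT"
    BAIT_BAIT = "BAIT_BAIT"


class Condition(str, enum.Enum):
    CONTROL = "control"
    ETOH_STRESS = "etoh_stress"


class FALevel(str, enum.Enum):
    """Formaldehyde crosslinker level, percent w/v. Metadata only."""

    FA_02 = "fa_0.2"
    FA_04 = "fa_0.4"


#: Row order within one replicate block, matching the pellet mixing table.
SAMPLE_TYPE_ORDER = (SampleType.WT_WT, SampleType.BAIT_WT, SampleType.BAIT_BAIT)

SAMPLE_SHEET_COLUMNS = [
    "sample_id",
    "sample_type",
    "condition",
    "fa_level",
    "replicate",
    "light_strain",
    "heavy_strain",
]


@dataclass(frozen=True)
class SampleSpec:
    """One mixed sample: a light and a heavy pellet sharing a replicate index."""

    sample_type: SampleType
    condition: Condition
    fa_level: FALevel
    replicate: int
    light_strain: str
    heavy_strain: str

    @property
    def sample_id(self) -> str:
        return (
            f"{self.sample_type.value}_{self.condition.value}_"
            f"{self.fa_level.value}_BR{self.replicate}"
        )


def _strains(
    sample_type: SampleType, replicate: int, wt: str, bait: str, label_swap: bool
) -> tuple[str, str]:
    br = f" BR{replicate}"
    if sample_type is SampleType.WT_WT:
        return wt + br, wt + br
    if sample_type is SampleType.BAIT_BAIT:
        return bait + br, bait + br
    # BAIT_WT: the tagged strain is grown light unless the design is swapped.
    if label_swap:
        return wt + br, bait + br
    return bait + br, wt + br


def enumerate_samples(
    conditions: Iterable[Condition | str],
    fa_levels: Iterable[FALevel | str],
    n_replicates: int,
    wt_label: str = "WT",
    bait_label: str = "Bait",
    label_swap: bool = False,
) -> list[SampleSpec]:
    """Enumerate the full factorial sample sheet.

    Ordering is condition-major, then crosslinker level, then replicate,
    then sample type in the order WT_WT, BAIT_WT, BAIT_BAIT (the pellet
    mixing-table row order). ``label_swap`` inverts which strain is grown
    in heavy medium for the BAIT_WT mix; the default (off) reflects the
    standard non-reciprocal layout.
    """
    conditions = [Condition(c) for c in conditions]
    fa_levels = [FALevel(f) for f in fa_levels]
    if not conditions or not fa_levels:
        raise InvalidDesignError("conditions and fa_levels must be non-empty")
    if len(set(conditions)) != len(conditions) or len(set(fa_levels)) != len(fa_levels):
        raise InvalidDesignError("duplicate condition or fa_level in design")
    if n_replicates < 1:
        raise InvalidDesignError(f"n_replicates must be >= 1, got {n_replicates}")

    out: list[SampleSpec] = []
    for cond in conditions:
        for fa in fa_levels:
            for rep in range(1, n_replicates + 1):
                for stype in SAMPLE_TYPE_ORDER:
                    light, heavy = _strains(stype, rep, wt_label, bait_label, label_swap)
                    out.append(
                        SampleSpec(
                            sample_type=stype,
                            condition=cond,
                            fa_level=fa,
                            replicate=rep,
                            light_strain=light,
                            heavy_strain=heavy,
                        )
                    )
    return out


def sample_sheet_frame(samples: Sequence[SampleSpec]) -> pd.DataFrame:
    """Tabular (TSV-ready) view of a sample list."""
    return pd.DataFrame(
        [
            {
                "sample_id": s.sample_id,
                "sample_type": s.sample_type.value,
                "condition": s.condition.value,
                "fa_level": s.fa_level.value,
                "replicate": s.replicate,
                "light_strain": s.light_strain,
                "heavy_strain": s.heavy_strain,
            }
            for s in samples
        ],
        columns=SAMPLE_SHEET_COLUMNS,
    )


def write_sample_sheet(samples: Sequence[SampleSpec], path) -> None:
    sample_sheet_frame(samples).to_csv(path, sep="\t", index=False)


def read_sample_sheet(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in df.columns]
    if missing:
        raise InvalidDesignError(f"sample sheet missing columns: {missing}")
    return df
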