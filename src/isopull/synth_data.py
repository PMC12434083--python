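"""Synthetic two-channel pull-down data with known ground truth.

The generator emulates the statistical structure the pipeline assumes:

* background proteins centered on L/H = 1 in every sample type;
* a bait and its interactors enriched — light channel up — only in the
  Bait/WT experiment, and absent from WT/WT runs entirely (the untagged
  strain purifies no bait, so there is nothing to quantify there);
* nonspecific binders (the biotinylated-carboxylase archetype) detected
  in every run at ratio 1;
* control decoys enriched both in the experiment and in one designated
  control sample type — the profile that the classifier's exclusion
  logic must catch;
* log-normal peptide noise (Gaussian on the log2 ratio scale), a shared
  per-run mixing error that the median normalization must recover, an
  ion-level missingness process, and a fraction of observations drawn
  above the identification q-value cutoff.

In Bait/WT runs the bait's heavy channel behaves like a background noise
floor, so its ratios are large but finite; that finite fold is the
``bait_fold`` parameter. Each run draws from its own random stream keyed
on (seed, sample_id), so adding runs never perturbs existing ones, and a
fixed seed yields byte-identical output files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .design_model import (
    Condition,
    FALevel,
    SampleType,
    enumerate_samples,
    sample_sheet_frame,
)
from .errors import ConfigError
from .report_io import ProteinDB, ProteinRecord

_PEPTIDE_ALPHABET = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


@dataclass(frozen=True)
class Interactor:
    """A protein enriched with the bait in Bait/WT runs.

    ``conditions`` restricts the enrichment to specific growth conditions
    (None = enriched under every condition); outside them the protein is
    still detected, at ratio 1.
    """

    accession: str
    fold: float
    conditions: tuple[str, ...] | None = None


@dataclass(frozen=True)
class ControlDecoy:
    """A protein enriched in the experiment and in one control sample type."""

    accession: str
    control_sample_type: str  # "WT_WT" or "BAIT_BAIT"
    fold: float


#: Enrichment tiers of a realistic bait pull-down: polymerase-core-like
#: partners in the tens, secondary partners in single digits.
DEFAULT_INTERACTORS = (
    Interactor("RPOB", 38.0),
    Interactor("RPOC", 37.0),
    Interactor("RPOA", 22.0),
    Interactor("GREA", 5.2),
    Interactor("CLPX", 3.5),
    Interactor("ACPA", 2.4),
)


@dataclass
class SimConfig:
    seed: int = 0
    n_background_proteins: int = 150
    n_replicates: int = 4
    conditions: tuple = (Condition.CONTROL.value,)
    fa_levels: tuple = (FALevel.FA_02.value,)
    bait_id: str = "SIGA_TS"
    bait_fold: float = 256.0
    include_bait: bool = True
    interactors: tuple = DEFAULT_INTERACTORS
    nonspecific_binders: tuple = ("PYCA",)
    control_decoys: tuple = ()
    peptide_count_range: tuple[int, int] = (10, 20)
    peptide_length_range: tuple[int, int] = (8, 18)
    peptide_noise_sd: float = 0.3
    replicate_mix_error_sd: float = 0.2
    missing_rate: float = 0.05
    q_fail_rate: float = 0.02
    q_value_max: float = 0.01
    #: bounds on emitted protein lengths; within them the length is set by
    #: the peptide content and a target coverage drawn in 45-75%
    protein_length_range: tuple[int, int] = (100, 900)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["interactors"] = [dataclasses.asdict(i) for i in self.interactors]
        d["control_decoys"] = [dataclasses.asdict(c) for c in self.control_decoys]
        return d


@dataclass
class SimData:
    """Simulated experiment plus its ground truth."""

    config: SimConfig
    report: pd.DataFrame
    sample_sheet: pd.DataFrame
    protein_db: ProteinDB
    truth_proteins: pd.DataFrame  # (protein_id, role, sample_type, condition) -> true_log2_fold, present
    truth_runs: pd.DataFrame  # sample_id -> injected mixing factor
    truth_peptides: pd.DataFrame  # peptide -> protein, 1-based start/end

    def write(self, out_dir) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "report": out / "report.tsv",
            "sample_sheet": out / "samples.tsv",
            "fasta": out / "proteins.fasta",
            "truth_proteins": out / "truth_proteins.tsv",
            "truth_runs": out / "truth_runs.tsv",
            "truth_peptides": out / "truth_peptides.tsv",
            "config": out / "sim_config.json",
        }
        self.report.to_csv(paths["report"], sep="\t", index=False, float_format="%.12g")
        self.sample_sheet.to_csv(paths["sample_sheet"], sep="\t", index=False)
        with open(paths["fasta"], "w") as fh:
            for pid, rec in self.protein_db.records.items():
                fh.write(f">{pid} {rec.description}\n")
                for i in range(0, len(rec.sequence), 60):
                    fh.write(rec.sequence[i : i + 60] + "\n")
        for key in ("truth_proteins", "truth_runs", "truth_peptides"):
            getattr(self, key).to_csv(paths[key], sep="\t", index=False, float_format="%.12g")
        paths["config"].write_text(json.dumps(self.config.to_dict(), indent=2, sort_keys=True))
        return paths


def _run_stream(seed: int, sample_id: str) -> np.random.Generator:
    """Independent stream per run, stable under run-set changes."""
    digest = hashlib.md5(sample_id.encode()).digest()
    return np.random.default_rng([seed, int.from_bytes(digest[:8], "little")])


def _protein_roster(config: SimConfig) -> list[tuple[str, str, float, tuple | None]]:
    """(accession, role, bait_wt_fold, enriched_conditions) in emission order."""
    roster: list[tuple[str, str, float, tuple | None]] = []
    if config.include_bait:
        roster.append((config.bait_id, "bait", config.bait_fold, None))
    for it in config.interactors:
        roster.append((it.accession, "interactor", it.fold, it.conditions))
    for dec in config.control_decoys:
        roster.append((dec.accession, "decoy", dec.fold, None))
    for acc in config.nonspecific_binders:
        roster.append((acc, "nonspecific", 1.0, None))
    for i in range(config.n_background_proteins):
        roster.append((f"BG{i + 1:04d}", "background", 1.0, None))
    ids = [r[0] for r in roster]
    dupes = {x for x in ids if ids.count(x) > 1}
    if dupes:
        raise ConfigError(f"accession collision in simulation roster: {sorted(dupes)}")
    return roster


def _make_proteins(config: SimConfig, rng: np.random.Generator, roster):
    """Random protein sequences with the simulated peptides embedded as true
    substrings; emitted length is peptide content / target coverage."""
    db = ProteinDB()
    pep_rows = []
    lo_n, hi_n = config.peptide_count_range
    lo_l, hi_l = config.peptide_length_range
    for acc, role, _, _ in roster:
        n_pep = int(rng.integers(lo_n, hi_n + 1))
        lengths = rng.integers(lo_l, hi_l + 1, size=n_pep)
        total = int(lengths.sum())
        cov_target = rng.uniform(0.45, 0.75)
        length = int(np.clip(round(total / cov_target), *config.protein_length_range))
        length = max(length, total)
        extra = length - total
        cuts = np.sort(rng.integers(0, extra + 1, size=n_pep))
        gaps = np.diff(np.concatenate([[0], cuts, [extra]]))
        peptides: list[str] = []
        while len(peptides) < n_pep:
            pep = "".join(rng.choice(_PEPTIDE_ALPHABET, size=int(lengths[len(peptides)])))
            if pep not in peptides:
                peptides.append(pep)
        parts, pos = [], 0
        for gap, pep in zip(gaps[:-1], peptides):
            parts.append("".join(rng.choice(_PEPTIDE_ALPHABET, size=int(gap))))
            pos += int(gap)
            parts.append(pep)
            pep_rows.append(
                {
                    "protein_id": acc,
                    "peptide_seq": pep,
                    "start": pos + 1,
                    "end": pos + len(pep),
                }
            )
            pos += len(pep)
        parts.append("".join(rng.choice(_PEPTIDE_ALPHABET, size=int(gaps[-1]))))
        db.records[acc] = ProteinRecord(acc, "".join(parts), f"simulated {role} protein")
    return db, pd.DataFrame(pep_rows, columns=["protein_id", "peptide_seq", "start", "end"])


def _true_log2_fold(role: str, bait_wt_fold: float, enriched_conditions,
                    decoy_control: str | None, sample_type: str, condition: str) -> float | None:
    """Planted log2 fold; None = protein absent from that sample type."""
    if role in ("bait", "interactor") and sample_type == SampleType.WT_WT.value:
        return None
    if role in ("bait", "interactor") and sample_type == SampleType.BAIT_WT.value:
        if enriched_conditions is None or condition in enriched_conditions:
            return float(np.log2(bait_wt_fold))
        return 0.0
    if role == "decoy":
        if sample_type in (SampleType.BAIT_WT.value, decoy_control):
            return float(np.log2(bait_wt_fold))
        return 0.0
    return 0.0


def simulate_experiment(config: SimConfig, out_dir=None) -> SimData:
    """Generate the peptide report, FASTA, sample sheet and ground truth."""
    decoy_controls = {d.accession: SampleType(d.control_sample_type).value
                      for d in config.control_decoys}

    roster = _protein_roster(config)
    structure_rng = np.random.default_rng([config.seed, 0])
    db, truth_peptides = _make_proteins(config, structure_rng, roster)

    samples = enumerate_samples(config.conditions, config.fa_levels, config.n_replicates)
    sheet = sample_sheet_frame(samples)

    pep_by_protein = {
        acc: grp["peptide_seq"].tolist()
        for acc, grp in truth_peptides.groupby("protein_id", sort=False)
    }

    truth_rows, run_rows, report_chunks = [], [], []
    for acc, role, fold, enr_conds in roster:
        for st in SAMPLE_TYPES_ORDERED:
            for cond in config.conditions:
                tlf = _true_log2_fold(role, fold, enr_conds, decoy_controls.get(acc), st, cond)
                truth_rows.append(
                    {
                        "protein_id": acc, "role": role, "sample_type": st,
                        "condition": cond, "present": tlf is not None,
                        "true_log2_fold": 0.0 if tlf is None else tlf,
                    }
                )

    for spec in samples:
        rng = _run_stream(config.seed, spec.sample_id)
        mix = float(rng.normal(0.0, config.replicate_mix_error_sd))
        run_rows.append(
            {"sample_id": spec.sample_id, "mix_error_log2": mix,
             "mix_factor": float(2.0 ** mix)}
        )
        recs = []
        for acc, role, fold, enr_conds in roster:
            tlf = _true_log2_fold(
                role, fold, enr_conds, decoy_controls.get(acc),
                spec.sample_type.value, spec.condition.value,
            )
            peptides = pep_by_protein[acc]
            n = len(peptides)
            if tlf is None:
                continue  # bait/interactors purify nothing in WT/WT runs
            observed = (
                np.ones(n, dtype=bool)
                if role == "nonspecific"
                else rng.uniform(size=n) >= config.missing_rate
            )
            noise = rng.normal(0.0, config.peptide_noise_sd, size=n)
            q_fail = rng.uniform(size=n) < config.q_fail_rate
            q = np.where(
                q_fail,
                rng.uniform(config.q_value_max * 1.01, 0.2, size=n),
                rng.uniform(1e-5, config.q_value_max * 0.99, size=n),
            )
            obs_log2 = tlf + mix + noise
            ratio_hl = 2.0 ** (-obs_log2)
            for i, pep in enumerate(peptides):
                if observed[i]:
                    recs.append((spec.sample_id, acc, pep, ratio_hl[i], q[i]))
        report_chunks.append(
            pd.DataFrame(recs, columns=["sample_id", "protein_id", "peptide_seq",
                                        "ratio_hl", "q_value"])
        )

    sim = SimData(
        config=config,
        report=pd.concat(report_chunks, ignore_index=True),
        sample_sheet=sheet,
        protein_db=db,
        truth_proteins=pd.DataFrame(truth_rows),
        truth_runs=pd.DataFrame(run_rows),
        truth_peptides=truth_peptides,
    )
    if out_dir is not None:
        sim.write(out_dir)
    return sim


SAMPLE_TYPES_ORDERED = (
    SampleType.WT_WT.value,
    SampleType.BAIT_WT.value,
    SampleType.BAIT_BAIT.value,
)


# ---------------------------------------------------------------------------
# canonical small fixtures


def smoke_config(seed: int = 11) -> SimConfig:
    """Ten background proteins, no noise: end-to-end recovery is exact."""
    return SimConfig(
        seed=seed,
        n_background_proteins=10,
        interactors=(
            Interactor("INT40", 40.0), Interactor("INT20", 20.0),
            Interactor("INT05", 5.0), Interactor("INT2P5", 2.5),
        ),
        nonspecific_binders=("PYCA",),
        peptide_noise_sd=0.0,
        replicate_mix_error_sd=0.0,
        missing_rate=0.0,
        q_fail_rate=0.0,
    )


def null_config(seed: int = 12) -> SimConfig:
    """Background only, noiseless: the exact null."""
    return SimConfig(
        seed=seed,
        n_background_proteins=50,
        include_bait=False,
        interactors=(),
        control_decoys=(),
        peptide_noise_sd=0.0,
        replicate_mix_error_sd=0.0,
        missing_rate=0.0,
        q_fail_rate=0.0,
    )


def tier_config(seed: int = 13, n_per_tier: int = 10) -> SimConfig:
    """Bait plus interactor tiers at folds 40/20/5/2.5 under default noise.

    Background proteins outnumber the enriched set ten to one so that the
    run medians driving normalization remain background-dominated, as in a
    real pull-down eluate.
    """
    tiers = []
    for fold, tag in ((40.0, "T40"), (20.0, "T20"), (5.0, "T05"), (2.5, "T2P5")):
        tiers.extend(Interactor(f"{tag}_{i:03d}", fold) for i in range(n_per_tier))
    return SimConfig(
        seed=seed,
        n_background_proteins=10 * (len(tiers) + 1),
        interactors=tuple(tiers),
    )


def single_tier_config(
    fold: float,
    seed: int,
    n_interactors: int = 200,
    n_background: int = 1800,
) -> SimConfig:
    """One enrichment tier at scale: ``n_interactors`` planted proteins at a
    common true fold against a 9x background, under default noise."""
    tag = str(fold).replace(".", "P")
    tiers = tuple(Interactor(f"F{tag}_{i:03d}", fold) for i in range(n_interactors))
    return SimConfig(seed=seed, n_background_proteins=n_background, interactors=tiers)


def decoy_config(seed: int = 14, n_decoys: int = 5) -> SimConfig:
    """Planted control-enriched decoys at fold 4, low noise."""
    decoys = tuple(
        ControlDecoy(f"DWT{i:02d}", SampleType.WT_WT.value, 4.0) for i in range(n_decoys)
    ) + tuple(
        ControlDecoy(f"DBB{i:02d}", SampleType.BAIT_BAIT.value, 4.0) for i in range(n_decoys)
    )
    return SimConfig(
        seed=seed,
        n_background_proteins=60,
        interactors=(Interactor("INT08", 8.0),),
        control_decoys=decoys,
        peptide_noise_sd=0.05,
        replicate_mix_error_sd=0.05,
        missing_rate=0.0,
        q_fail_rate=0.0,
    )


def tuning_fixture(n_replicates: int = 4):
    """Deterministic dataset whose bait has ion CV 0.28 and coverage 35%.

    Background peptides sit at exactly L/H = 1 so run medians are 1 and the
    bait's CV survives normalization unchanged; the bait's three peptides
    cover 70 of 200 residues (35.0% exactly) and its Bait/WT ratios
    alternate around the mean so the sample CV is exactly 0.28. Filter
    tuning on this dataset must therefore relax the thresholds to
    (ion_cv 0.3, seq_coverage 30).

    Returns (report, sample_sheet, protein_db).
    """
    alphabet = "ACDEFGHIKLMNPQRSTVY"  # no W: filler is poly-W

    def pep(i: int, length: int = 10) -> str:
        return "".join(alphabet[(i * 7 + j * 3 + i * i) % len(alphabet)] for j in range(length))

    samples = enumerate_samples([Condition.CONTROL], [FALevel.FA_02], n_replicates)
    sheet = sample_sheet_frame(samples)

    db = ProteinDB()
    background = {}
    for b in range(30):
        acc = f"BG{b + 1:04d}"
        peps = [pep(b * 10 + k) for k in range(6)]
        db.records[acc] = ProteinRecord(acc, "".join(peps), "background")
        background[acc] = peps
    bait_peps = [pep(900, 24), pep(901, 23), pep(902, 23)]  # 70 residues
    db.records["SIGA_TS"] = ProteinRecord(
        "SIGA_TS", "".join(bait_peps) + "W" * 130, "bait, coverage 35%"
    )

    a_over_m = 0.28 * np.sqrt(3.0) / 2.0  # sample CV of {m-a, m+a, m-a, m+a} = 0.28
    m = 50.0
    rows = []
    for spec in samples:
        sid = spec.sample_id
        for acc, peps in background.items():
            for p in peps:
                rows.append((sid, acc, p, 1.0, 0.001))
        if spec.sample_type is SampleType.BAIT_WT:
            lh = m * (1.0 - a_over_m) if spec.replicate % 2 else m * (1.0 + a_over_m)
            for p in bait_peps:
                rows.append((sid, "SIGA_TS", p, 1.0 / lh, 0.001))
        elif spec.sample_type is SampleType.BAIT_BAIT:
            for p in bait_peps:
                rows.append((sid, "SIGA_TS", p, 1.0, 0.001))
    report = pd.DataFrame(
        rows, columns=["sample_id", "protein_id", "peptide_seq", "ratio_hl", "q_value"]
    )
    return report, sheet, db


def make_fixture_suite(out_dir) -> dict[str, Path]:
    """Emit the canonical small datasets used for end-to-end checks."""
    out = Path(out_dir)
    paths = {}
    for name, cfg in (
        ("smoke", smoke_config()),
        ("null", null_config()),
        ("tiers", tier_config()),
        ("decoys", decoy_config()),
    ):
        sim = simulate_experiment(cfg, out / name)
        paths[name] = out / name
    tune_dir = out / "tuning"
    tune_dir.mkdir(parents=True, exist_ok=True)
    report, sheet, db = tuning_fixture()
    report.to_csv(tune_dir / "report.tsv", sep="\t", index=False, float_format="%.12g")
    sheet.to_csv(tune_dir / "samples.tsv", sep="\t", index=False)
    with open(tune_dir / "proteins.fasta", "w") as fh:
        for pid, rec in db.records.items():
            fh.write(f">{pid} {rec.description}\n{rec.sequence}\n")
    paths["tuning"] = tune_dir
    return paths
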