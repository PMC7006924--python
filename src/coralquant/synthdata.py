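"""Synthetic data generators with the statistical structure the pipeline
assumes.

The PSM generator emulates the study design: two independent iTRAQ 8-plex
runs (reporter tags 113-121), four treatments (ambient-seawater control,
methanol carrier control, purified brevetoxin, live K. brevis cells) in
biological tetraplicate (two replicate channels per treatment per run),
log-normal protein and peptide intensities, multiplicative biological and
measurement noise, spiked fold changes on a chosen fraction of proteins,
and a fraction of peptides shared between two proteins to exercise the
uniqueness filter. Flume-trial and phenotype generators mirror the
behavioral and physiological assays (10+ larvae per trial, n = 5 beakers
per treatment x time cell).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .diffabund import table1_fixture  # re-exported: the packaged result table
from .ecostats import OBS_PER_PERIOD, FlumePeriod, FlumeTrial, PhenotypeObservation
from .isoquant import ITRAQ8_CHANNELS, PlexDesign, PSMRecord
from .searchdb import TranscriptRecord

__all__ = [
    "SpikeSpec",
    "default_designs",
    "gen_transcripts",
    "gen_psm_experiment",
    "gen_flume",
    "gen_phenotypes",
    "table1_fixture",
]

_AMINO_ACIDS = "ACDEFGHILMNPQSTVWY"  # K/R reserved for tryptic C-termini


def default_designs() -> dict[str, PlexDesign]:
    """The 2-run x 8-plex tetraplicate layout: controls on 113/117,
    methanol on 114/118, brevetoxin on 115/119, K. brevis on 116/121;
    replicates 1-2 in run 1 and 3-4 in run 2."""
    tag_treatment = {
        "113": "control", "117": "control",
        "114": "MeOH", "118": "MeOH",
        "115": "PbTx", "119": "PbTx",
        "116": "Kbrevis", "121": "Kbrevis",
    }
    designs = {}
    for run_idx, run_id in enumerate(("run1", "run2")):
        seen: dict[str, int] = {}
        channel_map = {}
        for ch in ITRAQ8_CHANNELS:
            trt = tag_treatment[ch]
            seen[trt] = seen.get(trt, 0) + 1
            channel_map[ch] = (trt, str(2 * run_idx + seen[trt]))
        designs[run_id] = PlexDesign(
            run_id=run_id, channel_map=channel_map, control_channels=("113", "117")
        )
    return designs


def _cv_to_sd_log2(cv: float) -> float:
    # multiplicative noise: CV of a log-normal -> sd on the log2 scale
    return math.sqrt(math.log1p(cv**2)) / math.log(2)


@dataclass
class SpikeSpec:
    """Parameters of the synthetic iTRAQ experiment.

    Defaults reflect the emulated study: 500 proteins (a desk-scale
    subset of the ~1,290 quantified), spiked fold changes of 1.5 (the
    smallest change the published gates can call), peptide support of
    1-12 peptides per protein, 20% peptide-level measurement CV, 10%
    biological replicate CV, and a small shared-peptide fraction.
    """

    n_proteins: int = 500
    fraction_spiked: Mapping[str, float] = field(
        default_factory=lambda: {"MeOH": 0.05, "PbTx": 0.05, "Kbrevis": 0.1}
    )
    log2_effect: Mapping[str, float] = field(
        default_factory=lambda: {
            "MeOH": math.log2(1.5),
            "PbTx": math.log2(1.5),
            "Kbrevis": math.log2(1.5),
        }
    )
    prob_up: float = 0.7
    peptides_range: tuple[int, int] = (1, 12)
    spectra_range: tuple[int, int] = (1, 3)
    cv_measurement: float = 0.20
    cv_biological: float = 0.10
    shared_peptide_fraction: float = 0.05
    baseline_log2_mean: float = 10.0
    baseline_log2_sd: float = 1.5
    peptide_log2_sd: float = 1.2
    noise_floor: float = 300.0
    score_mean: float = 4.0
    score_sd: float = 2.0
    peptide_len_range: tuple[int, int] = (5, 20)
    seed: int = 0

    def __post_init__(self) -> None:
        for trt, f in self.fraction_spiked.items():
            if not 0 <= f <= 1:
                raise ValueError(f"fraction_spiked[{trt!r}]={f} outside [0, 1]")
        if self.cv_measurement < 0 or self.cv_biological < 0:
            raise ValueError("CVs must be non-negative")


def gen_transcripts(
    n: int,
    length: tuple[int, int] = (300, 1500),
    gc: float = 0.42,
    seed: int = 0,
    source: str = "synthetic",
) -> list[TranscriptRecord]:
    """Random nucleotide contigs with the given GC content."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= gc <= 1:
        raise ValueError(f"gc={gc} outside [0, 1]")
    rng = np.random.default_rng(seed)
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    bases = np.array(list("ACGT"))
    out = []
    for i in range(n):
        ln = int(rng.integers(length[0], length[1] + 1))
        seq = "".join(rng.choice(bases, size=ln, p=probs))
        out.append(TranscriptRecord(id=f"contig{i + 1}", sequence=seq, source=source))
    return out


def _random_peptide(rng, len_range: tuple[int, int]) -> str:
    ln = int(rng.integers(len_range[0], len_range[1] + 1))
    body = "".join(rng.choice(list(_AMINO_ACIDS), size=ln - 1))
    return body + ("K" if rng.random() < 0.5 else "R")


def gen_psm_experiment(
    spec: SpikeSpec, designs: Mapping[str, PlexDesign] | None = None
) -> tuple[list[PSMRecord], pd.DataFrame]:
    """Simulate PSM tables for the 2-run design plus a ground-truth table.

    Per protein a baseline log2 intensity is drawn; each peptide adds an
    ionization offset; each channel's intensity multiplies in the
    treatment fold change (for spiked proteins), a per-(protein,
    biological replicate) noise term and per-measurement noise at the
    stated CVs. Reporter S/N is intensity over the run noise floor. A
    stated fraction of peptides is assigned to a second protein.

    The ground-truth frame has one row per protein with each treatment's
    true status ('up', 'down' or 'ns') and true log2 fold change.
    """
    if designs is None:
        designs = default_designs()
    rng = np.random.default_rng(spec.seed)
    sd_meas = _cv_to_sd_log2(spec.cv_measurement)
    sd_bio = _cv_to_sd_log2(spec.cv_biological)
    treatments = sorted(spec.fraction_spiked)
    protein_ids = [f"P{i + 1:05d}" for i in range(spec.n_proteins)]

    truth_rows = []
    effects: dict[str, dict[str, float]] = {}
    for pid in protein_ids:
        row: dict[str, object] = {"protein_id": pid}
        effects[pid] = {}
        for trt in treatments:
            if rng.random() < spec.fraction_spiked[trt]:
                sign = 1.0 if rng.random() < spec.prob_up else -1.0
                eff = sign * spec.log2_effect[trt]
            else:
                eff = 0.0
            effects[pid][trt] = eff
            row[f"{trt}_log2fc"] = eff
            row[f"{trt}_status"] = "ns" if eff == 0 else ("up" if eff > 0 else "down")
        truth_rows.append(row)
    truth = pd.DataFrame(truth_rows)

    psms: list[PSMRecord] = []
    spectrum_counter = 0
    for p_idx, pid in enumerate(protein_ids):
        baseline = rng.normal(spec.baseline_log2_mean, spec.baseline_log2_sd)
        n_pep = int(rng.integers(spec.peptides_range[0], spec.peptides_range[1] + 1))
        peptides = []
        for _ in range(n_pep):
            pep = _random_peptide(rng, spec.peptide_len_range)
            owners = {pid}
            if spec.shared_peptide_fraction > 0 and rng.random() < spec.shared_peptide_fraction:
                other = protein_ids[int(rng.integers(spec.n_proteins))]
                if other != pid:
                    owners.add(other)
            peptides.append((pep, frozenset(owners), rng.normal(0, spec.peptide_log2_sd)))
        for run_id, design in sorted(designs.items()):
            # biological replicate noise: one draw per (protein, channel)
            bio = {
                ch: (rng.normal(0, sd_bio) if sd_bio > 0 else 0.0)
                for ch in design.channels
            }
            for pep, owners, offset in peptides:
                n_spec = int(
                    rng.integers(spec.spectra_range[0], spec.spectra_range[1] + 1)
                )
                for _ in range(n_spec):
                    spectrum_counter += 1
                    intensity = {}
                    sn = {}
                    for ch in design.channels:
                        trt, _rep = design.channel_map[ch]
                        eff = effects[pid].get(trt, 0.0)
                        log2_i = baseline + offset + eff + bio[ch]
                        if sd_meas > 0:
                            log2_i += rng.normal(0, sd_meas)
                        val = 2.0**log2_i
                        intensity[ch] = val
                        sn[ch] = val / spec.noise_floor
                    score = max(0.0, rng.normal(spec.score_mean, spec.score_sd))
                    psms.append(
                        PSMRecord(
                            spectrum_id=f"scan{spectrum_counter:07d}",
                            run_id=run_id,
                            peptide=pep,
                            proteins=owners,
                            score=score,
                            reporter_intensity=intensity,
                            reporter_sn=sn,
                        )
                    )
    return psms, truth


def gen_flume(
    n_larvae: int, p_cue: float, seed: int = 0, cue: str = "cue"
) -> list[FlumeTrial]:
    """Simulate side-swapped choice-flume trials: each 5-s observation
    is on the cue side with probability ``p_cue``."""
    if not 0 <= p_cue <= 1:
        raise ValueError(f"p_cue={p_cue} outside [0, 1]")
    rng = np.random.default_rng(seed)
    trials = []
    for i in range(n_larvae):
        periods = []
        for cue_side, other in (("left", "right"), ("right", "left")):
            obs = tuple(
                cue_side if rng.random() < p_cue else other
                for _ in range(OBS_PER_PERIOD)
            )
            periods.append(FlumePeriod(cue_side=cue_side, observations=obs))
        trials.append(
            FlumeTrial(larva_id=f"larva{i + 1}", cue=cue, periods=tuple(periods))
        )
    return trials


def gen_phenotypes(
    cell_means: Mapping[tuple[str, int], float],
    sd: float,
    n: int = 5,
    seed: int = 0,
    life_stage: str = "adult",
    proportion: bool = False,
) -> list[PhenotypeObservation]:
    """Gaussian draws around treatment x time cell means, n units per
    cell; proportions are clipped to [0, 1]."""
    if sd < 0:
        raise ValueError("sd must be non-negative")
    rng = np.random.default_rng(seed)
    out = []
    for (treatment, time_h), mean in sorted(cell_means.items()):
        for i in range(n):
            val = float(rng.normal(mean, sd)) if sd > 0 else float(mean)
            if proportion:
                val = min(1.0, max(0.0, val))
            out.append(
                PhenotypeObservation(
                    unit_id=f"{treatment}_{time_h}h_{i + 1}",
                    life_stage=life_stage,
                    treatment=treatment,
                    time_h=int(time_h),
                    response=val,
                )
            )
    return out
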