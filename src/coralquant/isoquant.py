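"""Isobaric (iTRAQ 8-plex) reporter-ion quantification.

One 8-plex run labels eight samples with reporter tags 113-121 (no 120);
each identified MS/MS spectrum (PSM) carries eight reporter intensities
and signal-to-noise values. Quantifiable spectra are filtered on
identification confidence, peptide uniqueness, peptide length and summed
reporter S/N; per-protein channel abundances are then expressed as ratios
against the mean of the two ambient-control channels, so each treated
channel becomes a fold estimate relative to control.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ITRAQ8_CHANNELS",
    "PlexDesign",
    "PSMRecord",
    "ProteinQuantRecord",
    "FilterTally",
    "ConcordanceReport",
    "filter_psms",
    "protein_channel_ratios",
    "control_concordance",
    "read_design_table",
    "write_design_table",
    "read_psm_table",
    "write_psm_table",
    "quant_to_frame",
]

#: The eight iTRAQ 8-plex reporter tags (121 replaces 120 in the kit).
ITRAQ8_CHANNELS = ("113", "114", "115", "116", "117", "118", "119", "121")

TREATMENTS = ("control", "MeOH", "PbTx", "Kbrevis")


@dataclass(frozen=True)
class PlexDesign:
    """Channel -> (treatment, biological replicate) map for one run."""

    run_id: str
    channel_map: Mapping[str, tuple[str, str]]
    control_channels: tuple[str, str] = ("113", "117")

    def __post_init__(self) -> None:
        channels = set(self.channel_map)
        if len(channels) != 8:
            raise ValueError(
                f"design {self.run_id!r}: expected 8 channels, got {len(channels)}"
            )
        if not set(self.control_channels) <= channels:
            raise ValueError(
                f"design {self.run_id!r}: control channels not in channel map"
            )
        pairs = list(self.channel_map.values())
        if len(set(pairs)) != len(pairs):
            raise ValueError(
                f"design {self.run_id!r}: duplicate (treatment, replicate) pair"
            )

    @property
    def channels(self) -> tuple[str, ...]:
        return tuple(sorted(self.channel_map))

    def treatment_channels(self, treatment: str) -> list[str]:
        return [
            ch
            for ch, (trt, _rep) in sorted(self.channel_map.items())
            if trt == treatment
        ]


@dataclass(frozen=True)
class PSMRecord:
    """One identified spectrum with its 8 reporter readouts."""

    spectrum_id: str
    run_id: str
    peptide: str
    proteins: frozenset[str]
    score: float
    reporter_intensity: Mapping[str, float]
    reporter_sn: Mapping[str, float]

    def __post_init__(self) -> None:
        if not self.peptide:
            raise ValueError(f"PSM {self.spectrum_id!r}: empty peptide")
        if self.score < 0:
            raise ValueError(f"PSM {self.spectrum_id!r}: negative score")
        object.__setattr__(self, "proteins", frozenset(self.proteins))


@dataclass
class ProteinQuantRecord:
    """Per-protein, per-run reporter ratios vs the control-channel mean.

    ``peptide_log_ratios`` keeps, per channel, the per-peptide log2
    ratios (peptide channel aggregate over that peptide's own control
    mean); downstream replicate tests consume these.
    """

    protein_id: str
    run_id: str
    channel_ratio: dict[str, float]
    n_spectra: int
    n_peptides: int
    peptide_log_ratios: dict[str, list[float]]
    n_zero_ratios: int = 0


@dataclass
class FilterTally:
    """Rejection bookkeeping from :func:`filter_psms`."""

    n_input: int = 0
    n_retained: int = 0
    rejected: Counter = field(default_factory=Counter)


@dataclass
class ConcordanceReport:
    """Between-control agreement check (|log2(c1/c2)| per protein)."""

    log2_diff: dict[str, float]
    flagged: list[str]
    tol_log2: float

    @property
    def fraction_flagged(self) -> float:
        return len(self.flagged) / len(self.log2_diff) if self.log2_diff else 0.0


def filter_psms(
    psms: Sequence[PSMRecord],
    min_score: float = 1.3,
    sn_sum_threshold: float = 9.0,
    min_pep_len: int = 6,
    designs: Mapping[str, PlexDesign] | None = None,
) -> tuple[list[PSMRecord], FilterTally]:
    """Apply the four quantifiability gates to PSMs, preserving order.

    A PSM is retained iff score >= ``min_score``, it maps to exactly one
    protein, its peptide has at least ``min_pep_len`` residues, and the
    sum of reporter signal-to-noise across channels is strictly greater
    than ``sn_sum_threshold``. If ``designs`` is given, a PSM reporting a
    channel absent from its run's design is a structural error.
    """
    if min_score < 0 or sn_sum_threshold < 0 or min_pep_len < 0:
        raise ValueError("thresholds must be non-negative")
    tally = FilterTally(n_input=len(psms))
    kept: list[PSMRecord] = []
    for psm in psms:
        if designs is not None:
            design = designs.get(psm.run_id)
            if design is None:
                raise ValueError(f"PSM {psm.spectrum_id!r}: unknown run {psm.run_id!r}")
            extra = (set(psm.reporter_intensity) | set(psm.reporter_sn)) - set(
                design.channel_map
            )
            if extra:
                raise ValueError(
                    f"PSM {psm.spectrum_id!r}: channels {sorted(extra)} absent "
                    f"from design of run {psm.run_id!r}"
                )
        reasons = []
        if psm.score < min_score:
            reasons.append("low_score")
        if len(psm.proteins) != 1:
            reasons.append("shared_peptide")
        if len(psm.peptide) < min_pep_len:
            reasons.append("short_peptide")
        if sum(psm.reporter_sn.values()) <= sn_sum_threshold:
            reasons.append("low_sn_sum")
        if reasons:
            tally.rejected.update(reasons)
        else:
            kept.append(psm)
    tally.n_retained = len(kept)
    return kept, tally


def _aggregate(values: list[float], how: str) -> float:
    if how == "sum":
        return float(sum(values))
    if how == "median":
        return float(np.median(values))
    raise ValueError(f"unknown aggregate {how!r}")


def protein_channel_ratios(
    psms: Sequence[PSMRecord],
    design: PlexDesign | Mapping[str, PlexDesign],
    aggregate: str = "sum",
) -> tuple[list[ProteinQuantRecord], list[str]]:
    """Roll filtered PSMs up to per-protein channel ratios.

    Per protein and run, reporter intensities are aggregated (sum by
    default, median optional) across its spectra per channel; the
    denominator is the arithmetic mean of the two control-channel
    aggregates, and every channel's ratio is aggregate/denominator.
    Channels with zero aggregate get ratio 0 and are excluded from the
    per-peptide log2-ratio lists (counted in ``n_zero_ratios``).

    Returns the quant records and the ids of proteins excluded because
    both control aggregates were zero (ratio undefined).
    """
    designs: Mapping[str, PlexDesign]
    if isinstance(design, PlexDesign):
        designs = {design.run_id: design}
    else:
        designs = design
    grouped: dict[tuple[str, str], list[PSMRecord]] = {}
    for psm in psms:
        if len(psm.proteins) != 1:
            raise ValueError(
                f"PSM {psm.spectrum_id!r} maps to {len(psm.proteins)} proteins; "
                "run filter_psms first"
            )
        if psm.run_id not in designs:
            raise ValueError(f"PSM {psm.spectrum_id!r}: unknown run {psm.run_id!r}")
        (protein,) = psm.proteins
        grouped.setdefault((protein, psm.run_id), []).append(psm)

    records: list[ProteinQuantRecord] = []
    excluded: list[str] = []
    for (protein, run_id), group in sorted(grouped.items()):
        des = designs[run_id]
        channels = des.channels
        per_channel = {
            ch: _aggregate([p.reporter_intensity.get(ch, 0.0) for p in group], aggregate)
            for ch in channels
        }
        c1, c2 = des.control_channels
        denom = (per_channel[c1] + per_channel[c2]) / 2.0
        if denom == 0:
            excluded.append(f"{protein} (run {run_id}): both control aggregates zero")
            continue
        ratios = {ch: per_channel[ch] / denom for ch in channels}

        # per-peptide log2 ratios against that peptide's own control mean
        by_peptide: dict[str, list[PSMRecord]] = {}
        for p in group:
            by_peptide.setdefault(p.peptide, []).append(p)
        log_ratios: dict[str, list[float]] = {ch: [] for ch in channels}
        n_zero = 0
        for pep_group in by_peptide.values():
            pep_channel = {
                ch: _aggregate(
                    [p.reporter_intensity.get(ch, 0.0) for p in pep_group], aggregate
                )
                for ch in channels
            }
            pep_denom = (pep_channel[c1] + pep_channel[c2]) / 2.0
            if pep_denom == 0:
                n_zero += len(channels)
                continue
            for ch in channels:
                if pep_channel[ch] > 0:
                    log_ratios[ch].append(math.log2(pep_channel[ch] / pep_denom))
                else:
                    n_zero += 1
        records.append(
            ProteinQuantRecord(
                protein_id=protein,
                run_id=run_id,
                channel_ratio=ratios,
                n_spectra=len(group),
                n_peptides=len(by_peptide),
                peptide_log_ratios=log_ratios,
                n_zero_ratios=n_zero,
            )
        )
    return records, excluded


def control_concordance(
    quants: Iterable[ProteinQuantRecord],
    designs: Mapping[str, PlexDesign],
    tol_log2: float = 1.0,
) -> ConcordanceReport:
    """Check that the two ambient-control channels agree per protein.

    Computes |log2(ratio_c1 / ratio_c2)| per protein/run (equal to the
    log ratio of the raw aggregates, since both share the denominator)
    and flags records exceeding ``tol_log2``.
    """
    diffs: dict[str, float] = {}
    flagged: list[str] = []
    for q in quants:
        c1, c2 = designs[q.run_id].control_channels
        key = f"{q.protein_id}@{q.run_id}"
        r1, r2 = q.channel_ratio[c1], q.channel_ratio[c2]
        if r1 <= 0 or r2 <= 0:
            diffs[key] = math.inf
            flagged.append(key)
            continue
        d = abs(math.log2(r1 / r2))
        diffs[key] = d
        if d > tol_log2:
            flagged.append(key)
    return ConcordanceReport(log2_diff=diffs, flagged=flagged, tol_log2=tol_log2)


# ---------------------------------------------------------------------------
# Tab-separated interchange formats
# ---------------------------------------------------------------------------
#
# Design table columns: run_id, channel, treatment, replicate, is_control
# PSM table columns: spectrum_id, run_id, peptide, proteins
#   (';'-separated), score, intensity_<ch> and sn_<ch> per channel.


def write_design_table(designs: Mapping[str, PlexDesign], path) -> None:
    rows = []
    for design in designs.values():
        for ch, (trt, rep) in sorted(design.channel_map.items()):
            rows.append(
                {
                    "run_id": design.run_id,
                    "channel": ch,
                    "treatment": trt,
                    "replicate": rep,
                    "is_control": int(ch in design.control_channels),
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_design_table(path) -> dict[str, PlexDesign]:
    df = pd.read_csv(path, sep="\t", dtype={"channel": str, "replicate": str})
    designs = {}
    for run_id, sub in df.groupby("run_id", sort=True):
        channel_map = {
            row.channel: (row.treatment, row.replicate) for row in sub.itertuples()
        }
        controls = tuple(sub.channel[sub.is_control == 1])
        if len(controls) != 2:
            raise ValueError(
                f"design {run_id!r}: expected exactly 2 control channels"
            )
        designs[str(run_id)] = PlexDesign(
            run_id=str(run_id), channel_map=channel_map, control_channels=controls
        )
    return designs


def write_psm_table(psms: Iterable[PSMRecord], path) -> None:
    rows = []
    for p in psms:
        row = {
            "spectrum_id": p.spectrum_id,
            "run_id": p.run_id,
            "peptide": p.peptide,
            "proteins": ";".join(sorted(p.proteins)),
            "score": p.score,
        }
        for ch in ITRAQ8_CHANNELS:
            row[f"intensity_{ch}"] = p.reporter_intensity.get(ch, 0.0)
            row[f"sn_{ch}"] = p.reporter_sn.get(ch, 0.0)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_psm_table(path) -> list[PSMRecord]:
    df = pd.read_csv(path, sep="\t")
    psms = []
    for row in df.itertuples():
        psms.append(
            PSMRecord(
                spectrum_id=str(row.spectrum_id),
                run_id=str(row.run_id),
                peptide=row.peptide,
                proteins=frozenset(str(row.proteins).split(";")),
                score=float(row.score),
                reporter_intensity={
                    ch: float(getattr(row, f"intensity_{ch}")) for ch in ITRAQ8_CHANNELS
                },
                reporter_sn={
                    ch: float(getattr(row, f"sn_{ch}")) for ch in ITRAQ8_CHANNELS
                },
            )
        )
    return psms


def quant_to_frame(quants: Iterable[ProteinQuantRecord]) -> pd.DataFrame:
    """Protein x channel ratio table with support counts, for TSV export."""
    rows = []
    for q in quants:
        row = {"protein_id": q.protein_id, "run_id": q.run_id}
        for ch in sorted(q.channel_ratio):
            row[f"ratio_{ch}"] = q.channel_ratio[ch]
        row["n_peptides"] = q.n_peptides
        row["n_spectra"] = q.n_spectra
        rows.append(row)
    return pd.DataFrame(rows)
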