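"""Differential protein abundance via Fisher's combined probability.

A protein is called differentially concentrated for a treatment when it
is quantified with at least three peptides in biological tetraplicates,
its Fisher's combined probability across replicate-level tests is below
0.05, and its fold change relative to the control-channel mean is above
1.5 or below 0.5 (all inequalities strict, as the gates are stated).

The replicate-level p-values entering Fisher's combination come from a
two-sided one-sample test of the peptide-level log2 ratios against zero
(t-test by default, Wilcoxon signed-rank optional): the identification
software behind the original workflow does not expose its internal test,
so both plausible conventions are available.
"""

from __future__ import annotations

import hashlib
import importlib.resources
import io
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .isoquant import PlexDesign, ProteinQuantRecord

__all__ = [
    "ReplicateTest",
    "DifferentialCall",
    "SetPartition",
    "fisher_combined",
    "replicate_pvalues",
    "classify",
    "classify_from_summary",
    "differential_calls",
    "partition",
    "table1_fixture",
    "table1_reanalysis",
    "calls_to_frame",
]

TABLE1_SHA256 = "83c745de07758e6fdaf215bcd3f72269d8345c6276b881da1aa1cb3e98847d8c"
TABLE1_ROWS = 61


@dataclass(frozen=True)
class ReplicateTest:
    """One protein x treatment x biological-replicate channel test."""

    protein_id: str
    treatment: str
    replicate: str
    log2_ratio: float
    pvalue: float
    n_peptide_ratios: int
    flag: str = ""

    def __post_init__(self) -> None:
        if not (0 < self.pvalue <= 1):
            raise ValueError(
                f"{self.protein_id}/{self.treatment}/{self.replicate}: "
                f"p-value {self.pvalue} outside (0, 1]"
            )


@dataclass(frozen=True)
class DifferentialCall:
    protein_id: str
    treatment: str
    fold_change: float
    combined_p: float
    n_peptides: int
    n_replicates: int
    status: str  # 'up' | 'down' | 'ns'
    reason: str = ""


@dataclass
class SetPartition:
    """Set algebra over two treatments' significant protein sets."""

    treatment_a: str
    treatment_b: str
    significant_a: set[str]
    significant_b: set[str]
    up_a: set[str] = field(default_factory=set)
    down_a: set[str] = field(default_factory=set)
    up_b: set[str] = field(default_factory=set)
    down_b: set[str] = field(default_factory=set)

    @property
    def shared(self) -> set[str]:
        return self.significant_a & self.significant_b

    @property
    def union(self) -> set[str]:
        return self.significant_a | self.significant_b

    @property
    def unique_up_a(self) -> set[str]:
        return self.up_a - self.significant_b

    @property
    def unique_down_a(self) -> set[str]:
        return self.down_a - self.significant_b

    @property
    def unique_up_b(self) -> set[str]:
        return self.up_b - self.significant_a

    @property
    def unique_down_b(self) -> set[str]:
        return self.down_b - self.significant_a


def fisher_combined(pvalues: Sequence[float]) -> tuple[float, int, float]:
    """Pool independent p-values: chi2 = -2 sum(ln p_i), df = 2k.

    Returns (chi2, df, combined p). A single p-value returns itself.
    """
    if len(pvalues) == 0:
        raise ValueError("fisher_combined: empty p-value list")
    for p in pvalues:
        if not (0 < p <= 1):
            raise ValueError(f"fisher_combined: p-value {p} outside (0, 1]")
    chi2 = -2.0 * sum(math.log(p) for p in pvalues)
    df = 2 * len(pvalues)
    return chi2, df, float(stats.chi2.sf(chi2, df))


def _one_sample_p(ratios: np.ndarray, test: str) -> tuple[float, str]:
    """Two-sided p for H0: mean log2 ratio = 0, with degenerate handling."""
    if len(ratios) < 2:
        return 1.0, "untestable"
    if np.allclose(ratios, ratios[0]):
        if ratios[0] == 0:
            return 1.0, "all_zero"
        return 1.0, "degenerate_variance"
    if test == "t_one_sample":
        p = float(stats.ttest_1samp(ratios, 0.0).pvalue)
    elif test == "wilcoxon":
        p = float(stats.wilcoxon(ratios).pvalue)
    else:
        raise ValueError(f"unknown test {test!r}")
    if math.isnan(p):
        return 1.0, "degenerate_variance"
    return max(p, np.finfo(float).tiny), ""


def replicate_pvalues(
    quants: Iterable[ProteinQuantRecord],
    designs: Mapping[str, PlexDesign],
    test: str = "t_one_sample",
) -> list[ReplicateTest]:
    """Per protein x treated replicate channel: test peptide log2 ratios
    against zero.

    Control channels are skipped (their ratios define the denominator).
    Channels with fewer than two peptide ratios are reported with p = 1
    and flagged ``untestable``; zero-variance channels get p = 1 with a
    ``degenerate_variance`` flag.
    """
    out: list[ReplicateTest] = []
    for q in quants:
        design = designs[q.run_id]
        for ch, (treatment, replicate) in sorted(design.channel_map.items()):
            if ch in design.control_channels:
                continue
            ratios = np.asarray(q.peptide_log_ratios.get(ch, []), dtype=float)
            if len(ratios) == 0:
                continue
            p, flag = _one_sample_p(ratios, test)
            out.append(
                ReplicateTest(
                    protein_id=q.protein_id,
                    treatment=treatment,
                    replicate=replicate,
                    log2_ratio=float(ratios.mean()),
                    pvalue=p,
                    n_peptide_ratios=len(ratios),
                    flag=flag,
                )
            )
    return out


def classify(
    tests: Sequence[ReplicateTest],
    support: tuple[int, int],
    alpha: float = 0.05,
    fc_up: float = 1.5,
    fc_down: float = 0.5,
    min_peptides: int = 3,
    min_replicates: int = 4,
) -> DifferentialCall:
    """Combine one protein x treatment's replicate tests into a call.

    ``support`` is (n_peptides, n_replicates). Fold change is the
    geometric mean of replicate ratios (mean in log2 space); combined p
    is Fisher's method over the replicate p-values. Support gates are
    applied before significance: a protein failing them is 'ns' with
    reason ``insufficient_support``.
    """
    if not tests:
        raise ValueError("classify: no replicate tests")
    if not (fc_down < 1 < fc_up):
        raise ValueError("require fc_down < 1 < fc_up")
    proteins = {t.protein_id for t in tests}
    treatments = {t.treatment for t in tests}
    if len(proteins) != 1 or len(treatments) != 1:
        raise ValueError("classify expects tests for a single protein x treatment")
    n_peptides, n_replicates = support
    mean_log2 = float(np.mean([t.log2_ratio for t in tests]))
    fold_change = 2.0**mean_log2
    _chi2, _df, combined_p = fisher_combined([t.pvalue for t in tests])
    if n_peptides < min_peptides or n_replicates < min_replicates:
        status, reason = "ns", "insufficient_support"
    else:
        status, reason = _status(fold_change, combined_p, alpha, fc_up, fc_down)
    return DifferentialCall(
        protein_id=proteins.pop(),
        treatment=treatments.pop(),
        fold_change=fold_change,
        combined_p=combined_p,
        n_peptides=n_peptides,
        n_replicates=n_replicates,
        status=status,
        reason=reason,
    )


def _status(
    fold_change: float, p: float, alpha: float, fc_up: float, fc_down: float
) -> tuple[str, str]:
    if p < alpha and fold_change > fc_up:
        return "up", ""
    if p < alpha and fold_change < fc_down:
        return "down", ""
    return "ns", ""


def classify_from_summary(
    fold_change: float,
    pvalue: float,
    alpha: float = 0.05,
    fc_up: float = 1.5,
    fc_down: float = 0.5,
) -> str:
    """Status from an already-summarized (fold change, p) pair, as when
    re-thresholding a published result table."""
    return _status(fold_change, pvalue, alpha, fc_up, fc_down)[0]


def differential_calls(
    quants: Sequence[ProteinQuantRecord],
    designs: Mapping[str, PlexDesign],
    treatments: Sequence[str] = ("MeOH", "PbTx", "Kbrevis"),
    test: str = "t_one_sample",
    alpha: float = 0.05,
    fc_up: float = 1.5,
    fc_down: float = 0.5,
    min_peptides: int = 3,
    min_replicates: int = 4,
) -> list[DifferentialCall]:
    """Run replicate tests and classification across all proteins.

    A protein's peptide support is the minimum distinct-peptide count
    across the runs it was quantified in; its replicate count is the
    number of treated channels contributing a testable peptide-ratio
    list across both runs.
    """
    reps = replicate_pvalues(quants, designs, test=test)
    support_pep: dict[str, int] = {}
    for q in quants:
        cur = support_pep.get(q.protein_id)
        support_pep[q.protein_id] = (
            q.n_peptides if cur is None else min(cur, q.n_peptides)
        )
    grouped: dict[tuple[str, str], list[ReplicateTest]] = {}
    for t in reps:
        grouped.setdefault((t.protein_id, t.treatment), []).append(t)
    calls = []
    for (protein, treatment), tests in sorted(grouped.items()):
        if treatment not in treatments:
            continue
        calls.append(
            classify(
                tests,
                support=(support_pep[protein], len(tests)),
                alpha=alpha,
                fc_up=fc_up,
                fc_down=fc_down,
                min_peptides=min_peptides,
                min_replicates=min_replicates,
            )
        )
    return calls


def partition(
    calls_a: Sequence[DifferentialCall], calls_b: Sequence[DifferentialCall]
) -> SetPartition:
    """Venn-style partition of two treatments' significant sets."""

    def index(calls: Sequence[DifferentialCall]) -> dict[str, DifferentialCall]:
        idx: dict[str, DifferentialCall] = {}
        for c in calls:
            if c.protein_id in idx:
                raise ValueError(f"duplicate protein id {c.protein_id!r}")
            idx[c.protein_id] = c
        return idx

    a, b = index(calls_a), index(calls_b)
    ta = calls_a[0].treatment if calls_a else "A"
    tb = calls_b[0].treatment if calls_b else "B"
    return SetPartition(
        treatment_a=ta,
        treatment_b=tb,
        significant_a={p for p, c in a.items() if c.status != "ns"},
        significant_b={p for p, c in b.items() if c.status != "ns"},
        up_a={p for p, c in a.items() if c.status == "up"},
        down_a={p for p, c in a.items() if c.status == "down"},
        up_b={p for p, c in b.items() if c.status == "up"},
        down_b={p for p, c in b.items() if c.status == "down"},
    )


def table1_fixture() -> pd.DataFrame:
    """Load the packaged 61-protein differential-abundance table
    (fold change and combined p per treatment, symbiont flag), verifying
    row count and checksum."""
    ref = importlib.resources.files("coralquant").joinpath("data/table1.tsv")
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != TABLE1_SHA256:
        raise ValueError(f"table1 fixture checksum mismatch: {digest}")
    df = pd.read_csv(io.BytesIO(raw), sep="\t")
    if len(df) != TABLE1_ROWS:
        raise ValueError(f"table1 fixture has {len(df)} rows, expected {TABLE1_ROWS}")
    return df


def table1_reanalysis(
    fixture: pd.DataFrame | None = None,
    alpha: float = 0.05,
    fc_up: float = 1.5,
    fc_down: float = 0.5,
) -> dict[str, int]:
    """Re-derive the headline differential-abundance counts by
    re-thresholding the packaged result table.

    Applies the published gates per treatment (PbTx and live K. brevis
    cells), partitions the significant sets, and returns totals,
    up/down splits, shared and unique sets, the union, and how many
    significant proteins are symbiont(Symbiodiniaceae)-derived.
    """
    df = table1_fixture() if fixture is None else fixture
    calls = {}
    for key, treatment in (("pbtx", "PbTx"), ("kbrevis", "Kbrevis")):
        calls[key] = [
            DifferentialCall(
                protein_id=row.gene_id,
                treatment=treatment,
                fold_change=getattr(row, f"{key}_fc"),
                combined_p=getattr(row, f"{key}_p"),
                n_peptides=-1,
                n_replicates=-1,
                status=classify_from_summary(
                    getattr(row, f"{key}_fc"),
                    getattr(row, f"{key}_p"),
                    alpha=alpha,
                    fc_up=fc_up,
                    fc_down=fc_down,
                ),
            )
            for row in df.itertuples()
        ]
    part = partition(calls["pbtx"], calls["kbrevis"])
    symbiont = set(df.gene_id[df.symbiont == 1])
    return {
        "pbtx_total": len(part.significant_a),
        "pbtx_up": len(part.up_a),
        "pbtx_down": len(part.down_a),
        "kbrevis_total": len(part.significant_b),
        "kbrevis_up": len(part.up_b),
        "kbrevis_down": len(part.down_b),
        "shared": len(part.shared),
        "union": len(part.union),
        "pbtx_unique_up": len(part.unique_up_a),
        "pbtx_unique_down": len(part.unique_down_a),
        "kbrevis_unique_up": len(part.unique_up_b),
        "kbrevis_unique_down": len(part.unique_down_b),
        "symbiont_significant": len(symbiont & part.union),
    }


def calls_to_frame(calls: Iterable[DifferentialCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "protein_id": c.protein_id,
                "treatment": c.treatment,
                "fold_change": c.fold_change,
                "combined_p": c.combined_p,
                "n_peptides": c.n_peptides,
                "n_replicates": c.n_replicates,
                "status": c.status,
                "reason": c.reason,
            }
            for c in calls
        ]
    )
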