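"""Normalization and cross-dataset comparison of the hyper-editing signal.

The comparable quantity across datasets of different depth is the number of
cluster-contained A→G mismatch events per million mapped bases (the
normalized hyper-editing signal). G→A clusters, found with identical
parameters, serve as the expected false-positive yardstick.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .detect import HyperEditedRead, TypeScreenReport

A_TO_G = ("A", "G")
T_TO_C = ("T", "C")
G_TO_A = ("G", "A")


class UndefinedSignalError(ZeroDivisionError):
    """Raised when a rate is requested with zero mapped bases."""


def normalized_signal(events: int, mapped_bases: int) -> float:
    """Editing events per million mapped bases."""
    if mapped_bases <= 0:
        raise UndefinedSignalError("normalized signal undefined for zero mapped bases")
    return events * 1e6 / mapped_bases


def specificity(report: TypeScreenReport, stranded: bool = False) -> float | None:
    """Fraction of unique cluster sites attributable to A-to-I editing.

    Unstranded libraries split true editing between A→G and T→C, so both
    count toward the numerator; stranded libraries count A→G only. Returns
    None when the screen found no sites of any type.
    """
    total = report.total("unique_sites")
    if total == 0:
        return None
    num = report.unique_sites.get(A_TO_G, 0)
    if not stranded:
        num += report.unique_sites.get(T_TO_C, 0)
    return num / total


@dataclass
class SignalReport:
    """Per-dataset signal summary in the style of the cross-species comparison."""

    label: str
    editing_events: int
    mapped_bases: int  # initially-mapped plus rescued hyper-edited read bases
    unique_sites: int
    pct_a_to_g_of_all_types: float | None
    false_positive_events: int = 0

    @property
    def normalized(self) -> float:
        return normalized_signal(self.editing_events, self.mapped_bases)

    @property
    def false_positive_signal(self) -> float:
        return normalized_signal(self.false_positive_events, self.mapped_bases)


def build_signal_report(
    label: str,
    per_type: dict[tuple[str, str], list[HyperEditedRead]],
    report: TypeScreenReport,
    initial_mapped_bases: int,
    stranded: bool = False,
) -> SignalReport:
    """Assemble a SignalReport from a 12-type screen.

    Mapped bases include the rescued hyper-edited reads (they are mapped
    after the transformed realignment); the effect of this choice is below
    1% either way at realistic editing abundances.
    """
    signal_types = [A_TO_G] if stranded else [A_TO_G, T_TO_C]
    fp_types = [G_TO_A] if stranded else [G_TO_A, ("C", "T")]
    events = sum(report.events.get(t, 0) for t in signal_types)
    fp_events = sum(report.events.get(t, 0) for t in fp_types)
    rescued_bases = sum(
        len(d.seq) for t in signal_types for d in per_type.get(t, [])
    )
    sites = sum(report.unique_sites.get(t, 0) for t in signal_types)
    spec = specificity(report, stranded=stranded)
    return SignalReport(
        label=label,
        editing_events=events,
        mapped_bases=initial_mapped_bases + rescued_bases,
        unique_sites=sites,
        pct_a_to_g_of_all_types=None if spec is None else 100.0 * spec,
        false_positive_events=fp_events,
    )


def compare_datasets(reports: list[SignalReport]) -> pd.DataFrame:
    """Rank datasets by normalized hyper-editing signal (ascending).

    The table mirrors the cross-species comparison: one row per dataset with
    the A→G signal and the G→A false-positive signal under identical
    parameters.
    """
    rows = [
        {
            "label": r.label,
            "editing_events": r.editing_events,
            "mapped_bases": r.mapped_bases,
            "normalized_signal": r.normalized,
            "false_positive_signal": r.false_positive_signal,
            "unique_sites": r.unique_sites,
            "pct_a_to_g_of_all_types": r.pct_a_to_g_of_all_types,
        }
        for r in reports
    ]
    df = pd.DataFrame(
        rows,
        columns=[
            "label",
            "editing_events",
            "mapped_bases",
            "normalized_signal",
            "false_positive_signal",
            "unique_sites",
            "pct_a_to_g_of_all_types",
        ],
    )
    if len(df):
        df = df.sort_values("normalized_signal", kind="stable").reset_index(drop=True)
    return df


def aggregate_replicates(reports: list[SignalReport], label: str) -> dict:
    """Mean ± standard error of the normalized signal over biological replicates."""
    import math

    vals = [r.normalized for r in reports]
    n = len(vals)
    if n == 0:
        raise ValueError("no replicates")
    mean = sum(vals) / n
    se = (
        math.sqrt(sum((v - mean) ** 2 for v in vals) / (n - 1)) / math.sqrt(n)
        if n > 1
        else 0.0
    )
    return {"label": label, "n_replicates": n, "mean_signal": mean, "se_signal": se}
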