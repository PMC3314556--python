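"""Aggregation of screening outcomes into the summary table.

One :class:`MagSummary` per species: candidate and final counts per
functional class, the functional subtotal, comparative-genomics gain and
loss counts, the overlap between the functional and gain routes, and a
grand total computed as ``final subtotal + gains + losses - overlap``.
The grand total is the invariant-consistent combination of the
components; all components are exposed so readers can recombine them.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import pandas as pd

from .candidates import FunctionalClass
from .classifier import MagDecision, MagStatus
from .gainloss import GainLossResult, render_ratio

__all__ = ["MagSummary", "summarize", "render_table", "render_gainloss_table"]

_CLASS_ORDER = (
    FunctionalClass.ETS_COMPLEX_I,
    FunctionalClass.NA_TRANSPORT,
    FunctionalClass.ABC_TRANSPORT,
    FunctionalClass.CHANNELS_PORES,
)

_CLASS_HEADERS = {
    FunctionalClass.ETS_COMPLEX_I: "ets_complex_i",
    FunctionalClass.NA_TRANSPORT: "na_transport",
    FunctionalClass.ABC_TRANSPORT: "abc_transport",
    FunctionalClass.CHANNELS_PORES: "channels_pores",
}


@dataclass(frozen=True)
class MagSummary:
    species: str
    candidate_counts: Mapping[FunctionalClass, int]
    final_counts: Mapping[FunctionalClass, int]
    gains: int = 0
    losses: int = 0
    overlap: int = 0

    def __post_init__(self) -> None:
        for counts in (self.candidate_counts, self.final_counts):
            if any(v < 0 for v in counts.values()):
                raise ValueError("counts must be nonnegative")
        if min(self.gains, self.losses, self.overlap) < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def candidate_subtotal(self) -> int:
        return sum(self.candidate_counts.get(c, 0) for c in _CLASS_ORDER)

    @property
    def final_subtotal(self) -> int:
        return sum(self.final_counts.get(c, 0) for c in _CLASS_ORDER)

    @property
    def grand_total(self) -> int:
        return self.final_subtotal + self.gains + self.losses - self.overlap


def summarize(
    decisions: Sequence[MagDecision],
    gainloss: Sequence[GainLossResult] = (),
    classes: Optional[Mapping[str, FunctionalClass]] = None,
    gains: Sequence[str] = (),
    losses: Sequence[str] = (),
    species: str = "",
) -> MagSummary:
    """Aggregate per-gene outcomes for one species.

    ``classes`` maps every functionally selected gene id to its class;
    a decided gene missing from it (and from the gain/loss lists) is an
    error. Overlap counts final functional MAGs that the gain screen also
    found.
    """
    classes = dict(classes or {})
    gain_set, loss_set = set(gains), set(losses)
    candidate_counts = {c: 0 for c in _CLASS_ORDER}
    final_counts = {c: 0 for c in _CLASS_ORDER}
    final_functional: set[str] = set()
    seen: set[str] = set()
    for d in decisions:
        if d.gene_id in seen:
            raise ValueError(f"duplicate decision for gene {d.gene_id!r}")
        seen.add(d.gene_id)
        cls = classes.get(d.gene_id)
        if cls is None:
            if d.gene_id in gain_set or d.gene_id in loss_set:
                continue
            raise ValueError(
                f"gene {d.gene_id!r} has no functional class and is not a "
                f"comparative-genomics candidate"
            )
        candidate_counts[cls] += 1
        if d.status is MagStatus.FINAL_MAG:
            final_counts[cls] += 1
            final_functional.add(d.gene_id)
    overlap = len(final_functional & gain_set)
    return MagSummary(
        species=species,
        candidate_counts=candidate_counts,
        final_counts=final_counts,
        gains=len(gain_set),
        losses=len(loss_set),
        overlap=overlap,
    )


def render_table(summaries: Sequence[MagSummary] | MagSummary) -> str:
    """Deterministic TSV in the summary-table column order."""
    if isinstance(summaries, MagSummary):
        summaries = [summaries]
    rows = []
    for s in summaries:
        for status, counts, subtotal in (
            ("candidate", s.candidate_counts, s.candidate_subtotal),
            ("final", s.final_counts, s.final_subtotal),
        ):
            row: dict[str, object] = {"species": s.species, "mag_status": status}
            for c in _CLASS_ORDER:
                row[_CLASS_HEADERS[c]] = counts.get(c, 0)
            row["subtotal"] = subtotal
            row["gene_gain"] = s.gains
            row["gene_loss"] = s.losses
            row["overlap"] = s.overlap
            row["total"] = s.grand_total
            rows.append(row)
    buf = io.StringIO()
    pd.DataFrame(rows).to_csv(buf, sep="\t", index=False)
    return buf.getvalue()


def render_gainloss_table(results: Sequence[GainLossResult]) -> str:
    """Per-gene gain/loss TSV with ratios at two significant figures."""
    rows = [
        {
            "gene_id": r.gene_id,
            "lca": r.lca_node,
            "losses": r.n_loss_min,
            "gains": r.n_gain_max,
            "ratio": render_ratio(r.ratio),
            "verdict": r.verdict.value,
        }
        for r in results
    ]
    buf = io.StringIO()
    pd.DataFrame(
        rows, columns=["gene_id", "lca", "losses", "gains", "ratio", "verdict"]
    ).to_csv(buf, sep="\t", index=False)
    return buf.getvalue()
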