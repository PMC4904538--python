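"""Normalisation of entry risks into percentage contributions.

Given an exposure history and a case configuration, each entry's absolute
risk is computed by :mod:`mesoapportion.risk_model`, and the percentage
contribution of entry *i* is ``risk_i / Σ_j risk_j × 100``.  Entries are
grouped by their free-text group label and subtotaled, producing a report
object ready for rendering.

Because percentages are ratios, any common rescaling of concentrations,
potencies or durations cancels: only relative values matter.  In
paper-truncate mode the per-entry integer truncation is applied *before*
summation and normalisation, so percentages are ratios of truncated
integers — this reproduces the original program's printout cell for cell.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

from .risk_model import (
    CaseConfig,
    EntryRisk,
    ExposureEntry,
    ValidationError,
    entry_risk,
    lagged_time,
)

__all__ = [
    "UNGROUPED_LABEL",
    "GroupSummary",
    "ApportionmentReport",
    "apportion",
    "sensitivity_over_potency",
]

#: Label under which entries with an empty group field are reported.
UNGROUPED_LABEL = "(ungrouped)"


@dataclass(frozen=True)
class GroupSummary:
    """A group label with its member entries and subtotals."""

    group: str
    members: tuple[EntryRisk, ...]
    subtotal_risk: float
    subtotal_percent: float


@dataclass(frozen=True)
class ApportionmentReport:
    """The assembled apportionment result.

    ``groups`` are ordered by first appearance of their label in the
    input (or relabelled order if the caller sorts them); ``entries``
    lists every :class:`EntryRisk` in report order (group by group).
    ``total_risk`` is the grand total over all entries, in the rounding
    mode of ``config``.
    """

    config: CaseConfig
    groups: tuple[GroupSummary, ...]
    total_risk: float

    @property
    def entries(self) -> tuple[EntryRisk, ...]:
        return tuple(er for g in self.groups for er in g.members)

    def group(self, label: str) -> GroupSummary:
        """Look up a group summary by its label."""
        for g in self.groups:
            if g.group == label:
                return g
        raise KeyError(label)


def apportion(
    entries: Sequence[ExposureEntry], config: CaseConfig
) -> ApportionmentReport:
    """Compute risks and percentage contributions for an exposure history.

    Parameters
    ----------
    entries:
        The exposure history; at least one entry, at least one of which
        must fall outside the latency lag window (otherwise the total
        risk is zero and no apportionment exists).
    config:
        Case configuration (diagnosis year, lag, exponent, plateau,
        rounding mode).

    Returns
    -------
    ApportionmentReport
        Groups ordered by first appearance of their label; entries within
        a group ordered by (year, input order).  Percentages sum to 100
        up to floating round-off.

    Raises
    ------
    ValidationError
        If the history is empty or no entry contributes positive risk.
    """
    if not entries:
        raise ValidationError("nothing to apportion: empty exposure history")

    scored = [
        EntryRisk(
            entry=e,
            lagged_time=lagged_time(e.year, config),
            risk=entry_risk(e, config),
        )
        for e in entries
    ]
    total = sum(er.risk for er in scored)
    if total <= 0:
        raise ValidationError(
            "no entry contributes risk (all exposures fall within the "
            f"{config.lag_years}-year latency lag); cannot apportion"
        )
    scored = [er.with_percent(er.risk / total * 100.0) for er in scored]

    # group by label, preserving first-appearance order; sort members by
    # (year, input order) — Python's sort is stable, so sorting the
    # enumerate-tagged list by year alone suffices
    order: list[str] = []
    buckets: dict[str, list[EntryRisk]] = {}
    for er in scored:
        label = er.entry.group or UNGROUPED_LABEL
        if label not in buckets:
            order.append(label)
            buckets[label] = []
        buckets[label].append(er)

    groups = []
    for label in order:
        members = sorted(buckets[label], key=lambda er: er.entry.year)
        groups.append(
            GroupSummary(
                group=label,
                members=tuple(members),
                subtotal_risk=sum(er.risk for er in members),
                subtotal_percent=sum(er.percent for er in members),
            )
        )
    return ApportionmentReport(
        config=config, groups=tuple(groups), total_risk=total
    )


def sensitivity_over_potency(
    entries: Sequence[ExposureEntry],
    config: CaseConfig,
    potency_overrides: Iterable[Mapping[str, float]],
) -> list[tuple[Mapping[str, float], ApportionmentReport]]:
    """Re-apportion under alternative relative-potency assumptions.

    Each override set maps group labels to positive multipliers applied to
    the potency of every entry in that group (e.g. re-running with a
    product treated as pure amphibole instead of a chrysotile/amphibole
    mix).  Only relative potencies matter to the result, so this is the
    natural sensitivity analysis: it shows how the apportionment moves as
    the assumed amphibole:chrysotile ratio changes.

    Returns one ``(override_set, report)`` pair per override set; the
    input entries are never mutated.

    Raises
    ------
    ValidationError
        If an override names a group label absent from the history.
    """
    known = {e.group or UNGROUPED_LABEL for e in entries}
    results: list[tuple[Mapping[str, float], ApportionmentReport]] = []
    for overrides in potency_overrides:
        unknown = set(overrides) - known
        if unknown:
            raise ValidationError(
                f"unknown group label(s) in potency overrides: "
                f"{sorted(unknown)}; known groups: {sorted(known)}"
            )
        for mult in overrides.values():
            if mult <= 0:
                raise ValidationError(
                    f"potency multiplier must be positive, got {mult}"
                )
        adjusted = [
            replace(
                e,
                potency=e.potency
                * overrides.get(e.group or UNGROUPED_LABEL, 1.0),
            )
            for e in entries
        ]
        results.append((overrides, apportion(adjusted, config)))
    return results
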