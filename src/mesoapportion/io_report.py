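"""Reading exposure histories, rendering reports, and fixture generation.

The interchange format is a plain UTF-8 CSV with a header row and columns
``year, months, concentration, potency, description, group`` plus an
optional ``end_year`` column: a row carrying a nonempty ``end_year`` is
expanded into one entry per calendar year of the range, mirroring how a
constant multi-year job exposure is entered once.

Reports render as human-readable text (the layout of the original
printout: entry rows grouped and subtotaled by group label, then a grand
total), as CSV, or as JSON carrying every field at full precision
alongside the display-rounded values.  Displayed percentages carry
exactly two decimals, rounded half-up, and are not force-balanced to
100.00; displayed risks are integers in paper-truncate mode.
"""

from __future__ import annotations

import csv
import io
import json
import logging
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path
from typing import IO, Iterable, Sequence

import numpy as np

from .apportionment import ApportionmentReport, GroupSummary, apportion
from .risk_model import (
    CaseConfig,
    ExposureEntry,
    RoundingMode,
    ValidationError,
    expand_range,
)

logger = logging.getLogger(__name__)

__all__ = [
    "REQUIRED_COLUMNS",
    "read_exposures",
    "write_exposures",
    "render_report",
    "round_half_up",
    "generate_history",
    "example_history",
    "example_config",
]

REQUIRED_COLUMNS = ("year", "months", "concentration", "potency")
OPTIONAL_COLUMNS = ("description", "group", "end_year")


def round_half_up(value: float, decimals: int = 2) -> float:
    """Round to ``decimals`` places with ties going up (display convention)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def _open_maybe(path_or_stream, mode: str):
    if hasattr(path_or_stream, "read") or hasattr(path_or_stream, "write"):
        return path_or_stream, False
    return open(path_or_stream, mode, encoding="utf-8", newline=""), True


def read_exposures(path_or_stream) -> list[ExposureEntry]:
    """Parse an exposure-history CSV into an ordered list of entries.

    Rows with a nonempty ``end_year`` are range-expanded.  Label
    whitespace is trimmed.  Errors name the offending row and column.
    """
    stream, should_close = _open_maybe(path_or_stream, "r")
    try:
        reader = csv.DictReader(stream)
        if reader.fieldnames is None:
            raise ValidationError("empty file: no header row")
        fields = [f.strip().lower() for f in reader.fieldnames]
        missing = [c for c in REQUIRED_COLUMNS if c not in fields]
        if missing:
            raise ValidationError(
                f"missing required column(s): {', '.join(missing)}"
            )
        entries: list[ExposureEntry] = []
        for lineno, raw in enumerate(reader, start=2):
            row = {
                k.strip().lower(): (v or "").strip()
                for k, v in raw.items()
                if k is not None
            }
            if not any(row.get(c) for c in REQUIRED_COLUMNS):
                logger.warning("row %d is blank; skipped", lineno)
                continue
            try:
                year = _parse_int(row, "year", lineno)
                months = _parse_float(row, "months", lineno)
                conc = _parse_float(row, "concentration", lineno)
                potency = _parse_float(row, "potency", lineno)
                description = row.get("description", "")
                group = row.get("group", "")
                end_raw = row.get("end_year", "")
                if end_raw:
                    end_year = _parse_int(row, "end_year", lineno)
                    if end_year < year:
                        raise ValidationError(
                            f"end_year {end_year} precedes year {year}"
                        )
                    entries.extend(
                        expand_range(
                            year, end_year, months, conc, potency,
                            description, group,
                        )
                    )
                else:
                    entries.append(
                        ExposureEntry(
                            year=year,
                            months=months,
                            concentration=conc,
                            potency=potency,
                            description=description,
                            group=group,
                        )
                    )
            except ValidationError as exc:
                raise ValidationError(f"row {lineno}: {exc}") from exc
        return entries
    finally:
        if should_close:
            stream.close()


def _parse_int(row: dict, col: str, lineno: int) -> int:
    try:
        return int(row[col])
    except (KeyError, ValueError):
        raise ValidationError(
            f"column '{col}': cannot parse {row.get(col, '')!r} as an integer"
        ) from None


def _parse_float(row: dict, col: str, lineno: int) -> float:
    try:
        return float(row[col])
    except (KeyError, ValueError):
        raise ValidationError(
            f"column '{col}': cannot parse {row.get(col, '')!r} as a number"
        ) from None


def write_exposures(entries: Sequence[ExposureEntry], path_or_stream) -> None:
    """Write entries as CSV at full precision (round-trips exactly)."""
    stream, should_close = _open_maybe(path_or_stream, "w")
    try:
        writer = csv.writer(stream)
        writer.writerow(list(REQUIRED_COLUMNS) + ["description", "group"])
        for e in entries:
            writer.writerow(
                [e.year, repr(e.months), repr(e.concentration),
                 repr(e.potency), e.description, e.group]
            )
    finally:
        if should_close:
            stream.close()


# ---------------------------------------------------------------------------
# report rendering


def _fmt_risk(risk: float, mode: RoundingMode) -> str:
    if mode is RoundingMode.PAPER_TRUNCATE:
        return str(int(risk))
    return f"{risk:.6g}"


def _fmt_num(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else f"{x:g}"


def render_report(
    report: ApportionmentReport, format: str = "text", sort: str = "input"
) -> str:
    """Render an apportionment report as ``text``, ``csv`` or ``json``.

    ``sort`` orders groups by first appearance in the input (``input``)
    or alphabetically by label (``label``).
    """
    if sort not in ("input", "label"):
        raise ValidationError(f"unknown sort order {sort!r}")
    groups = list(report.groups)
    if sort == "label":
        groups.sort(key=lambda g: g.group.casefold())
    if format == "text":
        return _render_text(report, groups)
    if format == "csv":
        return _render_csv(report, groups)
    if format == "json":
        return _render_json(report, groups)
    raise ValidationError(
        f"unknown format {format!r}; expected text, csv or json"
    )


def _render_text(report: ApportionmentReport, groups: list[GroupSummary]) -> str:
    mode = report.config.rounding_mode
    header = ["Year", "Months", "Conc.", "Potency", "Description",
              "Group", "Result", "Percent"]
    rows: list[list[str]] = []
    for g in groups:
        rows.append([f"Group description: {g.group}"])
        for er in g.members:
            e = er.entry
            rows.append([
                str(e.year), _fmt_num(e.months), _fmt_num(e.concentration),
                _fmt_num(e.potency), e.description, e.group,
                _fmt_risk(er.risk, mode), f"{round_half_up(er.percent):.2f}%",
            ])
        rows.append(["", "", "", "", "", "subtotal",
                     _fmt_risk(g.subtotal_risk, mode),
                     f"{round_half_up(g.subtotal_percent):.2f}%"])
        rows.append([])
    rows.append(["", "", "", "", "", "total",
                 _fmt_risk(report.total_risk, mode), "100.00%"])

    widths = [len(h) for h in header]
    for row in rows:
        if len(row) == len(header):
            widths = [max(w, len(c)) for w, c in zip(widths, row)]
    lines = [f"Mesothelioma diagnosis year: {report.config.diagnosis_year}"]
    cfg = report.config
    lines.append(
        f"Lag: {cfg.lag_years} y | time exponent: {_fmt_num(cfg.time_exponent)}"
        + (f" | plateau at {cfg.max_years} y since exposure"
           if cfg.max_years is not None else "")
        + f" | mode: {cfg.rounding_mode.value}"
    )
    lines.append("")
    lines.append("  ".join(h.ljust(w) for h, w in zip(header, widths)).rstrip())
    for row in rows:
        if len(row) == len(header):
            lines.append(
                "  ".join(c.ljust(w) for c, w in zip(row, widths)).rstrip()
            )
        else:
            lines.append(row[0] if row else "")
    return "\n".join(lines) + "\n"


def _render_csv(report: ApportionmentReport, groups: list[GroupSummary]) -> str:
    buf = io.StringIO()
    writer = csv.writer(buf)
    writer.writerow([
        "row_type", "group", "year", "months", "concentration", "potency",
        "description", "lagged_time", "risk", "percent",
        "risk_display", "percent_display",
    ])
    mode = report.config.rounding_mode
    for g in groups:
        for er in g.members:
            e = er.entry
            writer.writerow([
                "entry", g.group, e.year, repr(e.months),
                repr(e.concentration), repr(e.potency), e.description,
                repr(er.lagged_time), repr(er.risk), repr(er.percent),
                _fmt_risk(er.risk, mode), f"{round_half_up(er.percent):.2f}",
            ])
        writer.writerow([
            "subtotal", g.group, "", "", "", "", "", "",
            repr(g.subtotal_risk), repr(g.subtotal_percent),
            _fmt_risk(g.subtotal_risk, mode),
            f"{round_half_up(g.subtotal_percent):.2f}",
        ])
    writer.writerow([
        "total", "", "", "", "", "", "", "", repr(report.total_risk),
        repr(100.0), _fmt_risk(report.total_risk, mode), "100.00",
    ])
    return buf.getvalue()


def _render_json(report: ApportionmentReport, groups: list[GroupSummary]) -> str:
    cfg = report.config
    doc = {
        "config": {
            "diagnosis_year": cfg.diagnosis_year,
            "lag_years": cfg.lag_years,
            "time_exponent": cfg.time_exponent,
            "max_years": cfg.max_years,
            "rounding_mode": cfg.rounding_mode.value,
        },
        "total_risk": report.total_risk,
        "groups": [
            {
                "group": g.group,
                "subtotal_risk": g.subtotal_risk,
                "subtotal_percent": g.subtotal_percent,
                "subtotal_percent_display": round_half_up(g.subtotal_percent),
                "entries": [
                    {
                        "year": er.entry.year,
                        "months": er.entry.months,
                        "concentration": er.entry.concentration,
                        "potency": er.entry.potency,
                        "description": er.entry.description,
                        "group": er.entry.group,
                        "lagged_time": er.lagged_time,
                        "risk": er.risk,
                        "percent": er.percent,
                        "percent_display": round_half_up(er.percent),
                    }
                    for er in g.members
                ],
            }
            for g in groups
        ],
    }
    return json.dumps(doc, indent=2) + "\n"


# ---------------------------------------------------------------------------
# fixtures


def example_config(rounding_mode: RoundingMode = RoundingMode.PAPER_TRUNCATE) -> CaseConfig:
    """Configuration of the built-in worked example (diagnosis 2013)."""
    return CaseConfig(diagnosis_year=2013, rounding_mode=rounding_mode)


def example_history() -> list[ExposureEntry]:
    """The built-in worked example: 8 exposure periods, 1965–1970.

    A hypothetical worker handled an asbestos product ("Product A",
    potency 6 — roughly 90% chrysotile with 10% amphibole) in 1965, 1966
    and briefly in 1969, and worked around other chrysotile-only
    materials (potency 1) from 1966 to 1970; mesothelioma was diagnosed
    in 2013.  Shipped as ``data/table1_example.csv``.
    """
    text = (
        resources.files("mesoapportion")
        .joinpath("data/table1_example.csv")
        .read_text(encoding="utf-8")
    )
    return read_exposures(io.StringIO(text))


_POTENCY_CHOICES = np.array([1.0, 1.0, 1.0, 6.0, 35.0, 50.0, 100.0, 200.0, 500.0])


def generate_history(
    seed: int,
    n_entries: int,
    year_range: tuple[int, int],
    diagnosis_year: int,
    n_groups: int = 3,
) -> list[ExposureEntry]:
    """Deterministically generate a valid synthetic exposure history.

    Years are drawn uniformly from ``year_range`` (inclusive, must end
    before ``diagnosis_year``); months from half-month steps in (0, 12];
    concentrations from a lognormal spanning roughly two orders of
    magnitude (relative 8-h TWA values); potencies from the set of
    preset-like values {1, 6, 35, 50, 100, 200, 500} weighted toward
    chrysotile, reflecting its dominant historical use.  Group labels
    cycle through ``n_groups`` product names.  The same seed always
    yields the same history.
    """
    first, last = year_range
    if n_entries <= 0:
        raise ValidationError(f"n_entries must be positive, got {n_entries}")
    if n_groups <= 0:
        raise ValidationError(f"n_groups must be positive, got {n_groups}")
    if not (first <= last < diagnosis_year):
        raise ValidationError(
            f"require first <= last < diagnosis_year, got "
            f"{first} <= {last} < {diagnosis_year}"
        )
    rng = np.random.default_rng(seed)
    years = rng.integers(first, last + 1, size=n_entries)
    months = rng.integers(1, 25, size=n_entries) / 2.0  # 0.5 .. 12.0
    concentrations = np.round(rng.lognormal(0.0, 1.0, size=n_entries), 4)
    concentrations = np.maximum(concentrations, 1e-4)
    potencies = rng.choice(_POTENCY_CHOICES, size=n_entries)
    group_ids = rng.integers(0, n_groups, size=n_entries)
    return [
        ExposureEntry(
            year=int(y),
            months=float(m),
            concentration=float(c),
            potency=float(p),
            description=f"site {i % 4 + 1}",
            group=f"Product {chr(ord('A') + int(g))}",
        )
        for i, (y, m, c, p, g) in enumerate(
            zip(years, months, concentrations, potencies, group_ids)
        )
    ]
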