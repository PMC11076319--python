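"""Human-readable rendering of an analysis report.

Renders from the report's JSON-dict form so a saved report reloads and
re-renders identically (round-trip invariant).
"""

from __future__ import annotations

from typing import Sequence


def _section(title: str) -> list[str]:
    return ["", title, "-" * len(title)]


def render_text_report(report: dict) -> str:
    """Render the per-day x per-block matrix, detector statuses grouped by
    block, variability metrics and prioritized action flags as plain text."""
    lines: list[str] = []
    w = report["window"]
    lines.append(f"SMBG analysis report  [{w['start']} .. {w['end']}]")
    lines.append(f"input digest: {report['input_digest'][:16]}")

    suff = report["sufficiency"]
    lines += _section("Step 1: data sufficiency")
    lines.append(f"total tests: {suff['total_tests']}")
    lines.append(f"mean tests/day: {suff['mean_tests_per_day']:.2f}")
    lines.append(f"quantity ok: {suff['quantity_ok']}  quality ok: {suff['quality_ok']}")
    lines.append(f"pattern analysis active: {suff['pattern_analysis_active']}")
    for d in suff["deficiencies"]:
        lines.append(f"  deficiency: {d}")

    matrix = report["daily_block_matrix"]
    if matrix:
        blocks = list(next(iter(matrix.values())).keys())
        lines += _section("Tests per day and time block")
        lines.append("day        " + " ".join(f"{b:>9}" for b in blocks))
        for day in sorted(matrix):
            row = matrix[day]
            lines.append(day + " " + " ".join(f"{row[b]:>9d}" for b in blocks))

    lines += _section("Step 2: pattern detectors")
    findings = report["patterns"]
    red = [f for f in findings if f["status"] == "red"]
    if not red:
        lines.append("no patterns detected")
    current_block = None
    for f in findings:
        if f["block"] != current_block:
            current_block = f["block"]
            lines.append(f"[{current_block}]")
        tagline = f"  {f['detector']:<20} {f['status'].upper()}"
        if f["extra"].get("heuristic"):
            tagline += "  (heuristic)"
        lines.append(tagline)
        if f["status"] == "red":
            if "block" in f["extra"]:
                lines.append(f"    time block: {f['extra']['block']}")
            for e in f["evidence"]:
                lines.append(
                    f"    {e['timestamp']}  {e['value']:g} mg/dL  [{e['block']}]"
                )

    lines += _section("Step 3: variability and actions")
    var = report["variability"]
    if var is None:
        lines.append("variability undefined (fewer than 2 readings)")
    else:
        lines.append(
            f"mean {var['mean_glucose']:.1f} mg/dL  SD {var['sd']:.1f}  "
            f"CV {var['cv_percent']:.1f}%  LBGI {var['lbgi']:.2f}  HBGI {var['hbgi']:.2f}"
        )
        daily = var["daily_mean_cv_percent"]
        lines.append(
            "CV of mean daily glucose: "
            + ("n/a" if daily is None else f"{daily:.1f}%")
        )
        lines.append(f"variability class: {var['cv_class']} (gate basis: {var['gate_basis']})")
    if report["actions"]:
        lines.append("action flags (priority order):")
        for a in report["actions"]:
            lines.append(f"  - {a['code']}  (from: {', '.join(a['triggered_by'])})")
            lines.append(f"      {a['rationale']}")
    else:
        lines.append("no action flags")
    lines.append("")
    return "\n".join(lines)
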