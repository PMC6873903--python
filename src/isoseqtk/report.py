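"""Summary statistics report: per-stage counts and exact printed percentages.

Every percentage in a report is 100 x part / whole over counts present in
the same report, half-up rounded to two decimals, so any number in the
output can be re-derived from the counts next to it.
"""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP
from typing import Mapping


def pct(part: int | float, whole: int | float, decimals: int = 2) -> float:
    """100 * part / whole, half-up rounded (the rounding the tables print)."""
    if whole <= 0:
        raise ValueError("percentage denominator must be positive")
    q = Decimal(1).scaleb(-decimals)
    return float(
        (Decimal(str(part)) * 100 / Decimal(str(whole))).quantize(
            q, rounding=ROUND_HALF_UP
        )
    )


def _share_block(counts: Mapping[str, int]) -> dict:
    total = sum(counts.values())
    block = {"counts": dict(counts), "total": total}
    if total > 0:
        block["percent"] = {k: pct(v, total) for k, v in counts.items()}
    else:
        block["percent"] = {k: 0.0 for k in counts}
    return block


def summarize(
    roi_classes: Mapping[str, int] | None = None,
    transcript_categories: Mapping[str, int] | None = None,
    as_events: Mapping[str, int] | None = None,
    apa_sites_per_gene: Mapping[str, int] | None = None,
    lnc_categories: Mapping[str, int] | None = None,
    ssr_counts: Mapping[str, int] | None = None,
    ssr_scanned_bp: int | None = None,
    fusion_scopes: Mapping[str, int] | None = None,
    det_directions: Mapping[str, int] | None = None,
    expected_totals: Mapping[str, int] | None = None,
) -> dict:
    """Build the cross-stage summary report from per-stage count mappings.

    ``expected_totals`` optionally pins the total of a section (keyed by the
    argument name); a mismatch raises with the discrepancy spelled out.
    """
    report: dict = {}
    sections = {
        "roi_classes": roi_classes,
        "transcript_categories": transcript_categories,
        "as_events": as_events,
        "apa_sites_per_gene": apa_sites_per_gene,
        "lnc_categories": lnc_categories,
        "fusion_scopes": fusion_scopes,
        "det_directions": det_directions,
    }
    if not any(v is not None for v in sections.values()) and ssr_counts is None:
        raise ValueError("summarize needs at least one stage output")

    for name, counts in sections.items():
        if counts is None:
            continue
        block = _share_block(counts)
        if expected_totals and name in expected_totals:
            if block["total"] != expected_totals[name]:
                raise ValueError(
                    f"inconsistent totals for {name}: counted {block['total']}, "
                    f"expected {expected_totals[name]}"
                )
        report[name] = block

    if roi_classes is not None:
        total = sum(roi_classes.values())
        if total > 0:
            report["fl_percentage"] = pct(roi_classes.get("FLNC", 0), total)

    if apa_sites_per_gene is not None:
        multi = sum(v for k, v in apa_sites_per_gene.items() if k not in ("1",))
        total = sum(apa_sites_per_gene.values())
        if total > 0:
            report["apa_gene_percentage"] = pct(multi, total)

    if ssr_counts is not None:
        block: dict = {"counts": dict(ssr_counts), "total": sum(ssr_counts.values())}
        if ssr_scanned_bp:
            block["density_per_mb"] = {
                k: v * 1_000_000 / ssr_scanned_bp for k, v in ssr_counts.items()
            }
        report["ssr"] = block

    return report
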