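"""Headline tables: composition, loci, duplication profile, lineage sharing,
branch trajectory, and cross-species ratios.

All printed percentages and ratios use half-up decimal rounding at two
decimals and every table carries its own numerator/denominator columns so
each figure re-derives from the row it sits in.
"""

from __future__ import annotations

import json
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Mapping, Sequence

from nlrevo.classify import NLRAnnotation, summarize_composition
from nlrevo.cluster import LocusCall, locus_summary
from nlrevo.duptype import DuplicationCall, duplication_summary
from nlrevo.errors import ValidationError
from nlrevo.reconcile import BranchEvents


def nlr_count_ratios(
    counts: Mapping[str, int], reference_species: str
) -> dict[str, float]:
    """Per-species NLR count as a multiple of the reference, 2 decimals."""
    if reference_species not in counts:
        raise ValidationError(f"reference species {reference_species!r} missing")
    ref = counts[reference_species]
    if ref <= 0:
        raise ValidationError("reference count must be positive")
    out = {}
    for sp, n in counts.items():
        ratio = Decimal(n) / Decimal(ref)
        out[sp] = float(ratio.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))
    return out


def build_report(
    annotations: Mapping[str, Sequence[NLRAnnotation]],
    locus_calls: Mapping[str, Sequence[LocusCall]],
    dup_calls: Mapping[str, Sequence[DuplicationCall]] | None = None,
    lineage_summary: Mapping | None = None,
    branch_tally: Mapping[str, BranchEvents] | None = None,
    reference_species: str | None = None,
) -> dict:
    """Assemble one structured cross-species report with consistency checks.

    ``annotations`` and ``locus_calls`` are keyed by species.  Gene-id
    universes of the stages must agree per species; a mismatch raises a
    consistency error naming the offending ids.
    """
    species = sorted(annotations)
    report: dict = {"species": species, "composition": {}, "loci": {},
                    "checks": []}

    for sp in species:
        anns = list(annotations[sp])
        ann_ids = {a.gene_id for a in anns}
        calls = list(locus_calls.get(sp, []))
        call_ids = {c.gene_id for c in calls}
        if calls and ann_ids != call_ids:
            offenders = sorted(ann_ids ^ call_ids)
            raise ValidationError(
                f"{sp}: classification and locus stages disagree on gene ids: "
                f"{offenders[:10]}"
            )
        comp = summarize_composition(anns)
        report["composition"][sp] = {
            "total": len(anns),
            **{sub: comp[sub] for sub in comp},
        }
        check = sum(v["count"] for v in comp.values()) == len(anns)
        report["checks"].append(
            {"name": f"{sp}: subclass counts sum to total", "passed": check}
        )
        if calls:
            loci = locus_summary(calls)
            report["loci"][sp] = loci
            report["checks"].append({
                "name": f"{sp}: clustered+singleton+unmapped = total",
                "passed": loci["total"] == len(anns),
            })

    if dup_calls is not None:
        report["duplication"] = {}
        for sp in sorted(dup_calls):
            calls = list(dup_calls[sp])
            summary = duplication_summary(calls)
            report["duplication"][sp] = {
                "classified_total": len(calls),
                **summary,
            }
            report["checks"].append({
                "name": f"{sp}: duplication types partition mapped genes",
                "passed": sum(v["count"] for v in summary.values()) == len(calls),
            })

    if reference_species is not None:
        counts = {sp: len(annotations[sp]) for sp in species}
        report["count_ratios"] = {
            "reference": reference_species,
            "ratios": nlr_count_ratios(counts, reference_species),
        }

    if lineage_summary is not None:
        report["lineages"] = dict(lineage_summary)
    if branch_tally is not None:
        report["branch_events"] = {
            branch: {"gains": ev.gains, "losses": ev.losses,
                     "pattern": ev.pattern}
            for branch, ev in branch_tally.items()
        }

    report["all_checks_passed"] = all(c["passed"] for c in report["checks"])
    return report


def write_report(report: Mapping, out_dir: str | Path) -> Path:
    """Write report.json plus per-section TSVs; returns the JSON path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    json_path = out / "report.json"
    with open(json_path, "w") as handle:
        json.dump(report, handle, indent=1, sort_keys=True)

    comp_path = out / "composition.tsv"
    with open(comp_path, "w") as handle:
        handle.write("species\tsubclass\tcount\ttotal\tpercent\n")
        for sp, row in report.get("composition", {}).items():
            for sub in ("CNL", "TNL", "RNL"):
                if sub in row:
                    handle.write(
                        f"{sp}\t{sub}\t{row[sub]['count']}\t{row['total']}\t"
                        f"{row[sub]['percent']}\n"
                    )
    loci_path = out / "loci.tsv"
    with open(loci_path, "w") as handle:
        handle.write(
            "species\tclustered\tsingleton\tunmapped\tmapped_total\t"
            "clustered_pct\tsingleton_pct\n"
        )
        for sp, row in report.get("loci", {}).items():
            handle.write(
                f"{sp}\t{row['clustered']}\t{row['singleton']}\t"
                f"{row['unmapped']}\t{row['mapped_total']}\t"
                f"{row.get('clustered_pct', '')}\t{row.get('singleton_pct', '')}\n"
            )
    if "branch_events" in report:
        with open(out / "branch_events.tsv", "w") as handle:
            handle.write("branch\tgains\tlosses\tpattern\n")
            for branch, ev in report["branch_events"].items():
                handle.write(
                    f"{branch}\t{ev['gains']}\t{ev['losses']}\t{ev['pattern']}\n"
                )
    return json_path
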