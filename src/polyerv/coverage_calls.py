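"""WGS coverage-asymmetry evidence stream and the two-method intersection.

An annotated element is a coverage-based candidate private insertion
when one strain's library leaves more than ``min_reads`` unique reads
on it while the other library leaves none at all. The final call set
("potential polymorphic repetitive elements", ppREs) is the
intersection of the coverage stream with the assembly-comparison
stream; the three-way Venn counts are reported alongside.
"""

from __future__ import annotations

import pandas as pd

from .core import ERV_CLASS, ERV_FAMILIES, PpreCall, RepeatElement

__all__ = ["classify_by_coverage", "intersect_methods", "subset_ervs"]


def classify_by_coverage(table: pd.DataFrame, min_reads: int = 10) -> list[PpreCall]:
    """Coverage-evidence calls from a per-element read-count table.

    The rule is strict on both sides: ``count_S > min_reads`` in exactly
    one library and ``count == 0`` (no coverage at all) in the other.
    A count of exactly ``min_reads`` does not call.
    """
    required = {"element_id", "chrom", "start", "end", "subfamily", "family",
                "class", "count_A", "count_B"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"coverage table missing columns: {sorted(missing)}")
    if (table["count_A"] < 0).any() or (table["count_B"] < 0).any():
        raise ValueError("negative read counts")
    calls: list[PpreCall] = []
    for r in table.to_dict("records"):
        a, b = int(r["count_A"]), int(r["count_B"])
        if a > min_reads and b == 0:
            private_to = "A"
        elif b > min_reads and a == 0:
            private_to = "B"
        else:
            continue
        if "assembly" in r and r["assembly"] != private_to:
            # an element annotated in one assembly can only be private to
            # that assembly's strain; asymmetry pointing the other way is
            # an artifact (e.g. deletion) and is not a ppRE call
            continue
        element = RepeatElement(
            chrom=str(r["chrom"]), start=int(r["start"]), end=int(r["end"]),
            element_id=str(r["element_id"]), subfamily=str(r["subfamily"]),
            family=str(r["family"]), class_=str(r["class"]),
        )
        calls.append(PpreCall(element=element, private_to=private_to,
                              evidence_coverage=True))
    return calls


def intersect_methods(
    assembly_calls: dict[str, list[RepeatElement]],
    coverage_calls: list[PpreCall],
) -> tuple[list[PpreCall], dict[str, dict[str, int]]]:
    """Final ppRE calls: elements identified by both evidence streams.

    ``assembly_calls`` maps strain label -> elements called private to
    that strain by the assembly comparison. Returns the final calls and
    per-strain Venn counts (``assembly_only``, ``coverage_only``,
    ``both``), matched by element id.
    """
    cov_by_strain: dict[str, dict[str, PpreCall]] = {}
    for call in coverage_calls:
        cov_by_strain.setdefault(call.private_to, {})[call.element.element_id] = call

    final: list[PpreCall] = []
    venn: dict[str, dict[str, int]] = {}
    strains = sorted(set(assembly_calls) | set(cov_by_strain))
    for strain in strains:
        asm = {e.element_id: e for e in assembly_calls.get(strain, [])}
        cov = cov_by_strain.get(strain, {})
        both = sorted(set(asm) & set(cov))
        venn[strain] = {
            "assembly_only": len(set(asm) - set(cov)),
            "coverage_only": len(set(cov) - set(asm)),
            "both": len(both),
        }
        for eid in both:
            final.append(
                PpreCall(element=asm[eid], private_to=strain,
                         evidence_assembly=True, evidence_coverage=True,
                         final=True)
            )
    return final, venn


def subset_ervs(
    calls: list[PpreCall],
    erv_families: frozenset[str] = ERV_FAMILIES,
    erv_class: str = ERV_CLASS,
) -> list[PpreCall]:
    """Retain calls whose element is an ERV (LTR class, ERV family label)."""
    return [
        c for c in calls
        if c.element.class_ == erv_class and c.element.family in erv_families
    ]
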