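"""Summary tables and printed-ratio reproduction.

summarize() emits the four cohort tables (structural class x origin;
multiplicity histogram; intergenic subclass x origin x detection layer;
structural class x origin x detection layer). percentage_of() reproduces
printed percentages from a packaged fixture of published counts using
half-away-from-zero integer rounding.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .classify import multiplicity_table
from .integrate import EXPRESSION_SUBCLASSES
from .models import SV_CLASSES, UniqueSV

INTERGENIC_SUBCLASSES = (
    "promoter", "alt_5utr", "alt_3utr", "coding_fusion",
    "five_prime_truncated", "uncharacterized_rna",
)
INTRAGENIC_SUBCLASSES = (
    "intronic", "exonic_5utr", "exonic_3utr", "exonic_cds_disruptive",
    "exonic_noncoding",
)


@dataclass
class CountFixture:
    """Named integer counts transcribed from a published study's results,
    each with a source tag."""

    counts: dict[str, int]
    sources: dict[str, str]

    @classmethod
    def packaged(cls) -> "CountFixture":
        path = resources.files("svfw.data") / "paper_counts.tsv"
        df = pd.read_csv(path, sep="\t")
        counts = dict(zip(df["name"], df["count"].astype(int)))
        if any(v < 0 for v in counts.values()):
            raise ValueError("fixture counts must be non-negative")
        return cls(counts, dict(zip(df["name"], df["source"])))


def percentage_of(fixture: CountFixture, part_key: str, whole_key: str) -> int:
    """Integer percent, rounded half away from zero (exact integer arithmetic)."""
    for key in (part_key, whole_key):
        if key not in fixture.counts:
            raise KeyError(f"fixture has no count named {key!r}")
    part, whole = fixture.counts[part_key], fixture.counts[whole_key]
    if whole <= 0:
        raise ValueError("whole must be positive")
    return (200 * part + whole) // (2 * whole)


# ---------------------------------------------------------------------------
# cohort tables


def _cancer(svs: list[UniqueSV]) -> list[UniqueSV]:
    return [u for u in svs if u.origin in ("germline", "somatic")]


def class_origin_table(svs: list[UniqueSV]) -> pd.DataFrame:
    rows = []
    cancer = _cancer(svs)
    for origin in ("germline", "somatic"):
        of_origin = [u for u in cancer if u.origin == origin]
        for cls in SV_CLASSES:
            n = sum(1 for u in of_origin if u.sv_type == cls)
            rows.append(
                {
                    "sv_class": cls,
                    "origin": origin,
                    "count": n,
                    "percent": round(100.0 * n / len(of_origin), 1) if of_origin else 0.0,
                }
            )
    return pd.DataFrame(rows, columns=["sv_class", "origin", "count", "percent"])


def intergenic_table(svs: list[UniqueSV]) -> pd.DataFrame:
    """Intergenic subclass x origin with DNA, RNA-detected and differential
    columns (promoter rows carry NA in the RNA column and vice versa)."""
    rows = []
    cancer = [u for u in _cancer(svs) if u.location_class == "intergenic"]
    for origin in ("somatic", "germline"):
        for sub in INTERGENIC_SUBCLASSES:
            of = [u for u in cancer if u.origin == origin and u.subclass == sub]
            rna = sum(1 for u in of if u.expressed) if sub != "promoter" else pd.NA
            diff = (
                sum(1 for u in of if u.differential)
                if sub in EXPRESSION_SUBCLASSES
                else pd.NA
            )
            rows.append(
                {
                    "origin": origin,
                    "subclass": sub,
                    "dna": len(of),
                    "rna_detected": rna,
                    "differential": diff,
                }
            )
    return pd.DataFrame(rows, columns=["origin", "subclass", "dna", "rna_detected", "differential"])


def class_expression_table(svs: list[UniqueSV]) -> pd.DataFrame:
    """Structural class x origin over intergenic SVs: DNA count and
    RNA-detected-or-differential count."""
    rows = []
    cancer = [u for u in _cancer(svs) if u.location_class == "intergenic"]
    for origin in ("somatic", "germline"):
        for cls in SV_CLASSES:
            of = [u for u in cancer if u.origin == origin and u.sv_type == cls]
            rows.append(
                {
                    "origin": origin,
                    "sv_class": cls,
                    "dna": len(of),
                    "rna_or_differential": sum(1 for u in of if u.expressed or u.differential),
                }
            )
    return pd.DataFrame(rows, columns=["origin", "sv_class", "dna", "rna_or_differential"])


def summarize(svs: list[UniqueSV], n_samples: int) -> dict[str, pd.DataFrame]:
    """The four cohort tables; marginals are consistent by construction."""
    return {
        "class_origin": class_origin_table(svs),
        "multiplicity": multiplicity_table(_cancer(svs), n_samples),
        "intergenic": intergenic_table(svs),
        "class_expression": class_expression_table(svs),
    }
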