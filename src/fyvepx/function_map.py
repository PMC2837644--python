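"""COG-style functional roll-up of associated domains.

The shipped default mapping assigns each associated domain to one or more
of fifteen functional categories (thirteen adopted from the COG functional
classification plus protein-protein interaction and catalytic).  The
mapping is many-to-many: a domain such as PH belongs to both signal
transduction and cytoskeleton, and contributes its full association score
to each category it maps to — category totals may therefore exceed one.

The bare domain entry ``M`` in the function-unclear row is carried
verbatim from the source table and flagged as dubious.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from fyvepx.analysis import AssociationTable

UNASSIGNED = "unassigned"

#: entries carried verbatim from the source table despite looking truncated
DUBIOUS_DOMAINS = frozenset({"M"})

FunctionMap = dict[str, list[str]]


def load_function_map(path: str | Path | None = None) -> FunctionMap:
    """Load a domain -> categories mapping (two-column TSV, one row per pair).

    With no argument the packaged default table is used; pass a path to
    override it.  Category order per domain follows file order.
    """
    if path is None:
        source = resources.files("fyvepx.data").joinpath("function_categories.tsv")
        text = source.read_text()
    else:
        text = Path(path).read_text()
    mapping: FunctionMap = {}
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    header = lines[0].split("\t")
    if header[:2] != ["domain", "category"]:
        raise ValueError("function map must have columns: domain, category")
    for ln in lines[1:]:
        domain, category = ln.split("\t")[:2]
        cats = mapping.setdefault(domain, [])
        if category not in cats:
            cats.append(category)
    return mapping


def categorize(domain_name: str, mapping: FunctionMap) -> list[str]:
    """Return all categories of a domain; unmapped domains -> ["unassigned"]."""
    return list(mapping.get(domain_name, [UNASSIGNED]))


def category_summary(table: AssociationTable, mapping: FunctionMap) -> pd.DataFrame:
    """Sum association scores per functional category.

    Multi-category domains contribute their full score to every category
    they map to, so the summed-score column may total more than one.
    """
    totals: dict[str, float] = {}
    n = table.n_total
    for domain, count in table.counts.items():
        score = count / n
        for cat in categorize(domain, mapping):
            totals[cat] = totals.get(cat, 0.0) + score
    frame = pd.DataFrame(
        [{"category": c, "summed_score": s} for c, s in totals.items()],
        columns=["category", "summed_score"],
    )
    return frame.sort_values(
        ["summed_score", "category"], ascending=[False, True], ignore_index=True
    )
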