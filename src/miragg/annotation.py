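"""Identifier canonicalization and pathway ranking.

miRNA names change between nomenclature releases (e.g. ``hsa-miR-16``
became ``hsa-miR-16-5p``) and gene symbols have many synonyms, so
predictions and validation labels must be joined on canonical identifiers.
An :class:`AliasMap` rewrites aliases to their canonical form; identifiers
with no known alias pass through unchanged and are reported, never dropped.

Pathways are ranked for a given miRNA by the proportion of their member
genes the miRNA is predicted to target at a score threshold, with the count
of experimentally validated interactions attached per pathway.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = ["AliasMap", "canonicalize", "canonicalize_frame", "rank_pathways"]


@dataclass
class AliasMap:
    """alias -> canonical identifier mapping for miRNAs or genes.

    miRNA alias matching is case-insensitive (miRNA names are
    case-insensitive in practice); gene identifiers are matched exactly and
    treated as opaque strings.  Canonical identifiers are fixed points:
    mapping a canonical id returns itself.
    """

    entries: dict[str, str] = field(default_factory=dict)
    kind: str = "gene"

    def __post_init__(self) -> None:
        if self.kind not in ("mirna", "gene"):
            raise ValueError("kind must be 'mirna' or 'gene'")

    @classmethod
    def from_pairs(cls, pairs, kind: str) -> "AliasMap":
        m = cls(kind=kind)
        for alias, canonical in pairs:
            m.add(alias, canonical)
        return m

    def _key(self, alias: str) -> str:
        return alias.lower() if self.kind == "mirna" else alias

    def add(self, alias: str, canonical: str) -> None:
        key = self._key(alias)
        if key in self.entries and self.entries[key] != canonical:
            raise ValueError(
                f"alias {alias!r} maps to both {self.entries[key]!r} and {canonical!r}"
            )
        self.entries[key] = canonical
        # canonical ids are fixed points of the mapping
        ckey = self._key(canonical)
        if ckey in self.entries and self.entries[ckey] != canonical:
            raise ValueError(
                f"canonical id {canonical!r} collides with alias of {self.entries[ckey]!r}"
            )
        self.entries[ckey] = canonical

    def lookup(self, name: str) -> tuple[str, bool]:
        """Return (canonical_or_unchanged, was_mapped)."""
        key = self._key(name)
        if key in self.entries:
            return self.entries[key], True
        return name, False


def canonicalize(
    keys,
    mirna_map: AliasMap | None = None,
    gene_map: AliasMap | None = None,
):
    """Rewrite (mirna, gene) keys to canonical form.

    Unmapped identifiers pass through unchanged and are collected in the
    returned report ``{"mirna": [...], "gene": [...]}`` (unique, in first-seen
    order).  Applying the function twice is a no-op.
    """
    mirna_map = mirna_map or AliasMap(kind="mirna")
    gene_map = gene_map or AliasMap(kind="gene")
    out = []
    unmapped = {"mirna": [], "gene": []}
    seen = {"mirna": set(), "gene": set()}
    for mirna, gene in keys:
        new_m, ok_m = mirna_map.lookup(mirna)
        new_g, ok_g = gene_map.lookup(gene)
        if not ok_m and mirna not in seen["mirna"]:
            unmapped["mirna"].append(mirna)
            seen["mirna"].add(mirna)
        if not ok_g and gene not in seen["gene"]:
            unmapped["gene"].append(gene)
            seen["gene"].add(gene)
        out.append((new_m, new_g))
    return out, unmapped


def canonicalize_frame(df: pd.DataFrame, mirna_map=None, gene_map=None):
    """Canonicalize the ``mirna``/``gene`` columns of a table in one pass."""
    keys, report = canonicalize(zip(df["mirna"], df["gene"]), mirna_map, gene_map)
    out = df.copy()
    out["mirna"] = [m for m, _ in keys]
    out["gene"] = [g for _, g in keys]
    return out, report


def rank_pathways(
    targets: pd.DataFrame,
    pathways,
    validated: pd.DataFrame | None = None,
    threshold: float = 0.05,
    denominator: str = "all",
    universe: set[str] | None = None,
) -> pd.DataFrame:
    """Rank pathways by the proportion of their genes targeted by one miRNA.

    ``targets`` is an aggregated result table for a single miRNA; genes with
    score <= ``threshold`` count as targeted.  The proportion's denominator
    is every member gene of the pathway (``denominator="all"``) or only the
    member genes present in the prediction ``universe``
    (``denominator="universe"``).  Output is sorted by proportion descending,
    ties broken by pathway id; each row carries the number of the miRNA's
    experimentally validated interactions within the pathway.
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    if len(targets) == 0:
        raise ValueError("no targets supplied")
    mirnas = set(targets["mirna"])
    if len(mirnas) != 1:
        raise ValueError(f"targets must concern a single miRNA, found {sorted(mirnas)}")
    mirna = next(iter(mirnas))
    if denominator not in ("all", "universe"):
        raise ValueError("denominator must be 'all' or 'universe'")
    if denominator == "universe" and universe is None:
        universe = set(targets["gene"])

    hits = set(targets.loc[targets["score"] <= threshold, "gene"])
    validated_genes: set[str] = set()
    if validated is not None:
        validated_genes = set(validated.loc[validated["mirna"] == mirna, "gene"])

    rows = []
    for p in pathways:
        members = list(p.genes)
        if denominator == "universe":
            members = [g for g in members if g in universe]
        if len(p.genes) == 0:
            raise ValueError(f"pathway {p.pathway_id!r} has no member genes")
        targeted = [g for g in members if g in hits]
        n_valid = len([g for g in targeted if g in validated_genes])
        denom = len(members)
        rows.append(
            {
                "pathway_id": p.pathway_id,
                "name": p.name,
                "n_genes": denom,
                "n_targeted": len(targeted),
                "proportion": len(targeted) / denom if denom else 0.0,
                "n_validated": n_valid,
            }
        )
    out = pd.DataFrame(rows)
    out = out.sort_values(
        ["proportion", "pathway_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return out
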