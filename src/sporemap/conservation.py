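"""Cross-species hotspot conservation via ortholog-anchored synteny.

A source-species hotspot is associated with its five closest genes; their
orthologs in the target species define a projected interval when at least
two of them land within 10 kb of each other on one target chromosome.  A
projected hotspot is conserved when a target-species hotspot lies within
5 kb (edge-to-edge) of the projected interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

GENE_COLUMNS = ["gene", "chrom", "start", "end"]


@dataclass
class OrthologTable:
    """Gene coordinates in two species plus ortholog pairs.

    ``genes_a``/``genes_b``: DataFrames with columns gene, chrom, start,
    end.  ``pairs``: DataFrame with columns gene_a, gene_b.
    """

    genes_a: pd.DataFrame
    genes_b: pd.DataFrame
    pairs: pd.DataFrame

    def __post_init__(self) -> None:
        for name, df in (("genes_a", self.genes_a), ("genes_b", self.genes_b)):
            missing = [c for c in GENE_COLUMNS if c not in df.columns]
            if missing:
                raise ValueError(f"{name} missing columns: {missing}")
            if df["gene"].duplicated().any():
                raise ValueError(f"duplicate gene ids in {name}")
        known_a = set(self.genes_a["gene"])
        known_b = set(self.genes_b["gene"])
        bad = self.pairs[~self.pairs["gene_a"].isin(known_a) |
                         ~self.pairs["gene_b"].isin(known_b)]
        if len(bad):
            raise ValueError(f"{len(bad)} ortholog pairs reference unknown genes")


@dataclass
class SyntenyProjection:
    source_chrom: str
    source_start: int
    source_end: int
    anchor_genes: list[str]
    target_chrom: str | None
    target_start: int | None
    target_end: int | None

    @property
    def has_block(self) -> bool:
        return self.target_chrom is not None


def project_hotspot(
    hotspot: tuple[str, int, int],
    orthologs: OrthologTable,
    n_closest: int = 5,
    block_sep: int = 10_000,
) -> SyntenyProjection:
    """Project one source hotspot into the target species.

    The ``n_closest`` genes nearest the hotspot midpoint (ties broken by
    smaller gene start) are taken; among their target orthologs, any group
    of two or more lying within ``block_sep`` of each other on one target
    chromosome defines the projected interval (spanning the anchors).
    """
    chrom, start, end = hotspot
    mid = (start + end) / 2.0
    genes = orthologs.genes_a[orthologs.genes_a["chrom"] == chrom].copy()
    none = SyntenyProjection(chrom, start, end, [], None, None, None)
    if len(genes) == 0:
        return none
    gene_mid = (genes["start"] + genes["end"]) / 2.0
    genes["dist"] = (gene_mid - mid).abs()
    genes = genes.sort_values(["dist", "start"], kind="stable").head(n_closest)
    closest = list(genes["gene"])

    pairs = orthologs.pairs[orthologs.pairs["gene_a"].isin(closest)]
    targets = orthologs.genes_b[orthologs.genes_b["gene"].isin(pairs["gene_b"])]
    if len(targets) < 2:
        return SyntenyProjection(chrom, start, end, closest, None, None, None)
    for tchrom, grp in targets.groupby("chrom"):
        grp = grp.sort_values("start")
        # scan for >= 2 anchors pairwise within block_sep (gap between genes)
        rows = grp.to_dict("records")
        block: list[dict] = []
        best: list[dict] = []
        for g in rows:
            if block and g["start"] - block[-1]["end"] > block_sep:
                if len(block) > len(best):
                    best = block
                block = []
            block.append(g)
        if len(block) > len(best):
            best = block
        if len(best) >= 2:
            return SyntenyProjection(
                chrom, start, end, closest,
                str(tchrom), int(min(g["start"] for g in best)),
                int(max(g["end"] for g in best)),
            )
    return SyntenyProjection(chrom, start, end, closest, None, None, None)


def assess_conservation(
    projections: list[SyntenyProjection],
    target_hotspots: list[tuple[str, int, int]],
    max_sep: int = 5_000,
) -> pd.DataFrame:
    """Mark each projection conserved when a target hotspot lies nearby.

    Distance is edge-to-edge between the projected interval and the target
    hotspot interval (0 when they overlap); a projection is conserved when
    the distance is strictly less than ``max_sep``.  Returns one row per
    projection with the matched hotspot (if any); summary counts are in
    ``df.attrs``.
    """
    rows = []
    for pr in projections:
        matched = None
        best_d = None
        if pr.has_block:
            for chrom, s, e in target_hotspots:
                if chrom != pr.target_chrom:
                    continue
                d = max(0, max(pr.target_start - e, s - pr.target_end))
                if best_d is None or d < best_d:
                    best_d, matched = d, (chrom, s, e)
        conserved = best_d is not None and best_d < max_sep
        rows.append(dict(
            source_chrom=pr.source_chrom, source_start=pr.source_start,
            source_end=pr.source_end, projectable=pr.has_block,
            target_chrom=pr.target_chrom, target_start=pr.target_start,
            target_end=pr.target_end,
            distance=best_d if conserved else (best_d if best_d is not None else pd.NA),
            conserved=bool(conserved),
        ))
    df = pd.DataFrame(rows)
    df.attrs["n_projectable"] = int(df["projectable"].sum()) if len(df) else 0
    df.attrs["n_conserved"] = int(df["conserved"].sum()) if len(df) else 0
    return df
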