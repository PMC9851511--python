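"""On-disk formats.

Conventions: internal coordinates are 0-based half-open everywhere.  BED
files (masks, spot calls) are 0-based half-open as BED requires.  Genotype
and event TSVs carry 1-based positions (inclusive interval ends), matching
the supplementary-table style of tetrad studies; conversion happens only
here.  Missing genotypes are written as ``NA`` and never imputed.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import EventCatalog, MarkerMap, TetradSet, events_frame
from .genome import GenomeLayout, MaskSet
from .simulate import TruthCatalog

logger = logging.getLogger("sporemap")

SPORE_SUFFIXES = ("a", "b", "c", "d")

EVENT_TYPE_LABELS = {
    "co": "CO", "crossover": "CO",
    "nco": "NCO", "noncrossover": "NCO", "non-crossover": "NCO",
    "gc": "NCO", "gene_conversion": "NCO",
}


# ---------------------------------------------------------------- genotypes

def write_genotype_table(path: str | Path, tetrads: TetradSet) -> None:
    """Write the genotype TSV: chromosome, position (1-based), spore columns."""
    frames = []
    for chrom in tetrads.chromosomes:
        pos = tetrads.markers[chrom]
        g = tetrads.genotypes[chrom]  # (T, 4, M)
        data = {"chromosome": chrom, "position": pos + 1}
        cols = tetrads.spore_columns()
        arr = g.reshape(g.shape[0] * 4, g.shape[2])
        for i, col in enumerate(cols):
            data[col] = arr[i]
        frames.append(pd.DataFrame(data))
    df = pd.concat(frames, ignore_index=True)
    for col in tetrads.spore_columns():
        df[col] = df[col].map({0: "NA", 1: "1", 2: "2"})
    df.to_csv(path, sep="\t", index=False)


def read_genotype_table(path: str | Path) -> tuple[MarkerMap, TetradSet]:
    """Read the genotype TSV written by :func:`write_genotype_table`.

    Spore columns must come in groups of four sharing a tetrad-name prefix
    (``<tetrad>_<a..d>``); grouping is purely lexical.  Unsorted positions
    are sorted with a logged warning.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    df["position"] = df["position"].astype(np.int64)
    spore_cols = [c for c in df.columns if c not in ("chromosome", "position")]
    if len(spore_cols) % 4 != 0:
        raise ValueError(
            f"spore columns not a multiple of 4: {len(spore_cols)} "
            f"({spore_cols[:6]}...)"
        )
    tetrad_names: list[str] = []
    for i in range(0, len(spore_cols), 4):
        group = spore_cols[i:i + 4]
        prefixes = {c.rsplit("_", 1)[0] for c in group}
        suffixes = [c.rsplit("_", 1)[1] for c in group]
        if len(prefixes) != 1 or suffixes != list(SPORE_SUFFIXES):
            raise ValueError(
                f"spore columns {group} do not form a <tetrad>_<a..d> quartet"
            )
        tetrad_names.append(group[0].rsplit("_", 1)[0])

    positions: dict[str, np.ndarray] = {}
    genotypes: dict[str, np.ndarray] = {}
    for chrom, sub in df.groupby("chromosome", sort=False):
        if not sub["position"].is_monotonic_increasing:
            logger.warning("positions on %s were unsorted; sorting", chrom)
            sub = sub.sort_values("position")
        if sub["position"].duplicated().any():
            raise ValueError(f"duplicate marker positions on {chrom}")
        positions[chrom] = sub["position"].to_numpy(dtype=np.int64) - 1
        g = np.zeros((len(tetrad_names), 4, len(sub)), dtype=np.int8)
        for t, tet in enumerate(tetrad_names):
            for s, suf in enumerate(SPORE_SUFFIXES):
                col = sub[f"{tet}_{suf}"].str.strip()
                vals = col.map({"1": 1, "2": 2}).fillna(0).astype(np.int8)
                g[t, s] = vals.to_numpy()
        genotypes[chrom] = g
    markers = MarkerMap(positions)
    return markers, TetradSet(markers, tetrad_names, genotypes)


def read_genotype_vcf(
    path: str | Path, parent1: str, parent2: str
) -> tuple[MarkerMap, TetradSet]:
    """Convert a biallelic VCF into parental-origin codes.

    Sites where either parent is heterozygous or missing, where the parents
    agree, or with more than two alleles are dropped with a logged count.
    Spore samples must be named ``<tetrad>_<a..d>``.
    """
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover
        raise ImportError("VCF input requires the optional cyvcf2 dependency") from exc

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    for parent in (parent1, parent2):
        if parent not in samples:
            raise ValueError(f"parent sample {parent!r} not in VCF")
    spore_samples = [s for s in samples if s not in (parent1, parent2)]
    if len(spore_samples) % 4 != 0:
        raise ValueError("spore samples not a multiple of 4")
    i1, i2 = samples.index(parent1), samples.index(parent2)
    spore_idx = [samples.index(s) for s in spore_samples]

    rows = []
    dropped = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            dropped += 1
            continue
        gts = rec.genotypes  # [allele1, allele2, phased]
        g1, g2 = gts[i1], gts[i2]
        if g1[0] < 0 or g2[0] < 0 or g1[0] != g1[1] or g2[0] != g2[1] \
                or g1[0] == g2[0]:
            dropped += 1
            continue
        codes = []
        for si in spore_idx:
            a = gts[si][0]
            if a < 0:
                codes.append(0)
            elif a == g1[0]:
                codes.append(1)
            else:
                codes.append(2)
        rows.append((rec.CHROM, rec.POS - 1, codes))
    if dropped:
        logger.warning("dropped %d parent-uninformative VCF sites", dropped)

    tetrad_names = sorted({s.rsplit("_", 1)[0] for s in spore_samples})
    positions: dict[str, np.ndarray] = {}
    genotypes: dict[str, np.ndarray] = {}
    order = {f"{t}_{suf}": (ti, si) for ti, t in enumerate(tetrad_names)
             for si, suf in enumerate(SPORE_SUFFIXES)}
    by_chrom: dict[str, list] = {}
    for chrom, pos, codes in rows:
        by_chrom.setdefault(chrom, []).append((pos, codes))
    for chrom, items in by_chrom.items():
        items.sort()
        positions[chrom] = np.array([p for p, _ in items], dtype=np.int64)
        g = np.zeros((len(tetrad_names), 4, len(items)), dtype=np.int8)
        for m, (_, codes) in enumerate(items):
            for s_name, code in zip(spore_samples, codes):
                ti, si = order[s_name]
                g[ti, si, m] = code
        genotypes[chrom] = g
    markers = MarkerMap(positions)
    return markers, TetradSet(markers, tetrad_names, genotypes)


# ------------------------------------------------------------------- events

def write_event_table(path: str | Path, catalog: EventCatalog) -> None:
    """Write events as TSV with 1-based inclusive coordinates."""
    df = catalog.df.copy()
    for col in ("start", "pos"):
        df[col] = df[col].astype("int64") + 1
    df["tract_start"] = df["tract_start"] + 1
    df = df.rename(columns={"chrom": "chromosome", "kind": "type",
                            "cls": "class"})
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


DEFAULT_EVENT_COLUMNS = {
    "tetrad": "tetrad", "chromosome": "chromosome", "type": "type",
    "class": "class", "start": "start", "end": "end",
    "chromatids": "chromatids", "tract_start": "tract_start",
    "tract_end": "tract_end", "tract_len": "tract_len",
    "n_markers": "n_markers",
}


def read_event_table(
    path: str | Path, columns: dict[str, str] | None = None
) -> EventCatalog:
    """Read an event TSV (ReCombine-style export).

    ``columns`` maps the canonical names (keys of
    :data:`DEFAULT_EVENT_COLUMNS`) to the file's actual column names, since
    exports from different tools disagree on the schema.  Required: tetrad,
    chromosome, type, start, end.  Extra columns are preserved.  Event-type
    labels outside the accepted set raise an error.
    """
    colmap = dict(DEFAULT_EVENT_COLUMNS, **(columns or {}))
    df = pd.read_csv(path, sep="\t", dtype={colmap["chromosome"]: str},
                     na_values=["NA"])
    required = ["tetrad", "chromosome", "type", "start", "end"]
    missing = [k for k in required if colmap[k] not in df.columns]
    if missing:
        raise ValueError(f"event table missing required columns: {missing}")
    rename = {v: k for k, v in colmap.items() if v in df.columns}
    df = df.rename(columns=rename)

    if len(df):
        labels = df["type"].astype(str).str.strip().str.lower()
        unknown = sorted(set(labels) - set(EVENT_TYPE_LABELS))
        if unknown:
            raise ValueError(
                f"unknown event types {unknown}; accepted labels: "
                f"{sorted(set(EVENT_TYPE_LABELS))}"
            )
        df["kind"] = labels.map(EVENT_TYPE_LABELS)
    else:
        df["kind"] = pd.Series(dtype=str)
    df = df.rename(columns={"chromosome": "chrom", "class": "cls"})
    if len(df):
        df["start"] = df["start"].astype("int64") - 1
        df["end"] = df["end"].astype("int64")
        if "pos" in df.columns:
            df["pos"] = df["pos"].astype("int64") - 1
        else:
            df["pos"] = (df["start"] + df["end"]) // 2
        if "tract_start" in df.columns:
            df["tract_start"] = pd.to_numeric(df["tract_start"]) - 1
    out = events_frame(df.to_dict("records"))
    return EventCatalog(out, dict(source=str(path)))


def write_truth_table(path: str | Path, truth: TruthCatalog) -> None:
    df = truth.df.copy()
    df["truth"] = True
    df["pos"] = df["pos"].astype(float) + 1
    df["tract_start"] = df["tract_start"] + 1
    df = df.rename(columns={"chrom": "chromosome", "kind": "type"})
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


# --------------------------------------------------------------------- BED

def write_bed(
    path: str | Path,
    intervals: list[tuple],
    names: list[str] | None = None,
    scores: list[float] | None = None,
) -> None:
    """Write (chrom, start, end[, name, score]) intervals as BED."""
    with open(path, "w") as fh:
        for i, (chrom, start, end) in enumerate(intervals):
            fields = [str(chrom), str(int(start)), str(int(end))]
            if names is not None:
                fields.append(str(names[i]))
                if scores is not None:
                    fields.append(str(scores[i]))
            fh.write("\t".join(fields) + "\n")


def read_bed(path: str | Path) -> list[tuple[str, int, int]]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            out.append((parts[0], int(parts[1]), int(parts[2])))
    return out


def write_mask(path: str | Path, mask: MaskSet, layout: GenomeLayout) -> None:
    intervals = list(mask.intervals)
    for name in sorted(mask.excluded_chromosomes):
        intervals.append((name, 0, layout[name].length))
    write_bed(path, intervals)


def read_mask(
    path: str | Path, layout: GenomeLayout | None = None
) -> MaskSet:
    intervals = read_bed(path)
    excluded = set()
    if layout is not None:
        keep = []
        for chrom, start, end in intervals:
            if chrom in layout and start == 0 and end == layout[chrom].length:
                excluded.add(chrom)
            else:
                keep.append((chrom, start, end))
        intervals = keep
    return MaskSet(intervals=intervals, excluded_chromosomes=excluded)


# ------------------------------------------------------------------ config

def read_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping")
    return cfg


def write_summary(path: str | Path, summary: dict) -> None:
    """Machine-readable key-value stage summary (one ``key<TAB>value`` per line)."""
    with open(path, "w") as fh:
        for key, value in summary.items():
            if isinstance(value, float):
                fh.write(f"{key}\t{value:.6g}\n")
            elif isinstance(value, (dict, list)):
                continue
            else:
                fh.write(f"{key}\t{value}\n")
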