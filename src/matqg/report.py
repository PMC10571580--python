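"""Result assembly: Manhattan-plot tables, merged associated regions and
window-to-gene annotation from a user-supplied GFF3 (closed 1-based
coordinates, as GFF3 uses)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .geno_qc import Window, _chrom_key


class GFF3ParseError(ValueError):
    pass


def read_gff3_genes(path, feature_types: tuple = ("gene",)) -> pd.DataFrame:
    """Parse gene features from a GFF3 file.

    Returns columns chrom, start, end, gene_id, biotype, name.  Lines are
    validated first so a malformed line is reported with its number; the
    attribute column is parsed with gffutils.
    """
    import gffutils

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.rstrip("\n")
            if not s or s.startswith("#"):
                continue
            if len(s.split("\t")) != 9:
                raise GFF3ParseError(
                    f"{path}: line {lineno}: expected 9 tab-separated fields"
                )
    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    rows = []
    for ft in feature_types:
        for feat in db.features_of_type(ft):
            gene_id = feat.attributes.get("gene_id", [feat.id])[0]
            rows.append(
                {
                    "chrom": feat.seqid,
                    "start": feat.start,
                    "end": feat.end,
                    "gene_id": gene_id,
                    "biotype": feat.attributes.get(
                        "biotype", feat.attributes.get("gene_biotype", [""])
                    )[0],
                    "name": feat.attributes.get("Name", [gene_id])[0],
                }
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "gene_id", "biotype", "name"])


def manhattan_table(
    snp_table: pd.DataFrame,
    window_pct: pd.DataFrame | None = None,
    bf_threshold: float = 10.0,
) -> pd.DataFrame:
    """One row per SNP (chrom, pos, BF, window %), sorted by chromosome then
    position; the BF threshold is carried in ``attrs``."""
    required = {"marker", "chrom", "pos", "bf"}
    if not required.issubset(snp_table.columns):
        raise ValueError(f"snp_table needs columns {sorted(required)}")
    df = snp_table.copy()
    if window_pct is not None:
        df["mb_index"] = (df["pos"] - 1) // 1_000_000
        df = df.merge(
            window_pct[["chrom", "mb_index", "pct_var"]],
            on=["chrom", "mb_index"],
            how="left",
        ).drop(columns="mb_index")
    df["_ck"] = df["chrom"].map(_chrom_key)
    df = df.sort_values(["_ck", "pos"], kind="stable").drop(columns="_ck")
    df = df.reset_index(drop=True)
    df.attrs["bf_threshold"] = bf_threshold
    return df


@dataclass
class Region:
    """A run of adjacent associated 1-Mb windows on one chromosome."""

    chrom: str
    start_bp: int
    end_bp: int
    n_windows: int
    pct_var: float  # summed window percentages


def merge_consecutive_windows(window_calls: pd.DataFrame) -> list[Region]:
    """Merge runs of adjacent associated windows into regions.

    Input is the frame from ``call_associated_windows``; only rows with
    ``associated`` are used.  Windows with consecutive 1-Mb indices on the
    same chromosome form one region spanning min-start to max-end.
    """
    if window_calls.empty:
        return []
    assoc = window_calls.loc[window_calls["associated"]]
    regions: list[Region] = []
    for chrom, grp in assoc.groupby("chrom", sort=False):
        grp = grp.sort_values("mb_index")
        run = []
        prev = None
        for _, row in grp.iterrows():
            if prev is not None and row["mb_index"] != prev + 1:
                regions.append(_close_run(chrom, run))
                run = []
            run.append(row)
            prev = row["mb_index"]
        if run:
            regions.append(_close_run(chrom, run))
    regions.sort(key=lambda r: (_chrom_key(r.chrom), r.start_bp))
    return regions


def _close_run(chrom, run) -> Region:
    return Region(
        chrom=str(chrom),
        start_bp=int(run[0]["start_bp"]),
        end_bp=int(run[-1]["end_bp"]),
        n_windows=len(run),
        pct_var=float(sum(r["pct_var"] for r in run)),
    )


@dataclass
class AnnotatedRegion:
    trait: str
    chrom: str
    start_bp: int
    end_bp: int
    pct_var: float
    genes: list


def annotate_windows(
    regions: list[Region],
    genes: pd.DataFrame,
    trait: str = "",
    protein_coding_only: bool = False,
) -> list[AnnotatedRegion]:
    """Genes whose closed interval [start, end] intersects each region.

    A gene ending one bp before the region start (or starting one bp after
    its end) is excluded.  ``protein_coding_only`` filters on the GFF3
    biotype attribute.
    """
    if protein_coding_only and "biotype" in genes.columns:
        genes = genes.loc[genes["biotype"] == "protein_coding"]
    trees: dict[str, IntervalTree] = {}
    for _, g in genes.iterrows():
        # IntervalTree is half-open; +1 makes GFF3's closed end inclusive
        trees.setdefault(str(g["chrom"]), IntervalTree()).addi(
            int(g["start"]), int(g["end"]) + 1, g["gene_id"]
        )
    out = []
    for r in regions:
        tree = trees.get(str(r.chrom))
        hits = (
            sorted({iv.data for iv in tree.overlap(r.start_bp, r.end_bp + 1)})
            if tree is not None
            else []
        )
        out.append(
            AnnotatedRegion(
                trait=trait,
                chrom=r.chrom,
                start_bp=r.start_bp,
                end_bp=r.end_bp,
                pct_var=r.pct_var,
                genes=hits,
            )
        )
    return out


def regions_table(annotated: list[AnnotatedRegion]) -> pd.DataFrame:
    """Flat table of annotated regions (one row per region)."""
    return pd.DataFrame(
        [
            {
                "trait": a.trait,
                "chrom": a.chrom,
                "start_bp": a.start_bp,
                "end_bp": a.end_bp,
                "pct_var": a.pct_var,
                "n_genes": len(a.genes),
                "genes": ",".join(map(str, a.genes)),
            }
            for a in annotated
        ]
    )


def manhattan_plot(table: pd.DataFrame, out_path, trait: str = "") -> None:
    """Basic Manhattan plot of SNP Bayes factors with the threshold line."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    chroms = list(dict.fromkeys(table["chrom"]))
    offsets = {}
    off = 0
    for c in chroms:
        offsets[c] = off
        off += int(table.loc[table["chrom"] == c, "pos"].max()) + 1
    x = table["pos"].to_numpy() + np.array([offsets[c] for c in table["chrom"]])
    colors = [("#3b6ea5" if i % 2 == 0 else "#9a9a9a") for i, c in enumerate(chroms)]
    fig, ax = plt.subplots(figsize=(10, 3.2))
    for i, c in enumerate(chroms):
        m = (table["chrom"] == c).to_numpy()
        ax.scatter(x[m], table["bf"].to_numpy()[m], s=4, color=colors[i])
    ax.axhline(table.attrs.get("bf_threshold", 10.0), ls="--", color="black", lw=0.8)
    ax.set_xlabel("chromosome position")
    ax.set_ylabel("Bayes factor")
    if trait:
        ax.set_title(trait)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
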