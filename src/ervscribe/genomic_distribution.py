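"""Chromosomal distribution statistics and integration-context classification.

The null model assumes integrations land on chromosomes in proportion to
length: the expected count on chromosome ``c`` is ``e_c = L_c * n / sum(L)``.
Each chromosome's observed count is compared to its expectation with a
one-cell chi-square statistic ``(O - E)^2 / E`` on one degree of freedom;
no multiple-testing correction is applied by default (a Bonferroni option is
provided).  Solitary LTRs count as integrations alongside proviruses.

Context classification assigns each locus an intronic/exonic/intergenic call
(with sense/antisense orientation relative to the overlapping gene) from a
Gencode-dialect GTF, and a centromeric/pericentromeric flag from a UCSC
cytoBand table (acen stain).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

logger = logging.getLogger(__name__)

#: GRCh38 canonical chromosome lengths (bp), chr1-22, X, Y.
GRCH38_LENGTHS: dict[str, int] = {
    "chr1": 248956422, "chr2": 242193529, "chr3": 198295559, "chr4": 190214555,
    "chr5": 181538259, "chr6": 170805979, "chr7": 159345973, "chr8": 145138636,
    "chr9": 138394717, "chr10": 133797422, "chr11": 135086622, "chr12": 133275309,
    "chr13": 114364328, "chr14": 107043718, "chr15": 101991189, "chr16": 90338345,
    "chr17": 83257441, "chr18": 80373285, "chr19": 58617616, "chr20": 64444167,
    "chr21": 46709983, "chr22": 50818468, "chrX": 156040895, "chrY": 57227415,
}


def expected_counts(chrom_lengths: Mapping[str, int], n: int) -> pd.DataFrame:
    """Length-proportional expected integration counts per chromosome.

    Returns a frame with raw and nearest-integer-rounded expectations; the
    raw values sum to ``n`` exactly.
    """
    if not chrom_lengths:
        raise ValueError("empty chromosome length table")
    if n < 0:
        raise ValueError("n must be >= 0")
    chroms = list(chrom_lengths)
    lengths = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    raw = lengths * n / lengths.sum()
    return pd.DataFrame(
        {
            "chrom": chroms,
            "length": lengths.astype(int),
            "expected": raw,
            "expected_rounded": np.rint(raw).astype(int),
        }
    )


def chisq_per_chromosome(
    observed: Mapping[str, int],
    chrom_lengths: Mapping[str, int],
    n: int | None = None,
    alpha: float = 0.05,
    alpha_strict: float = 0.005,
    bonferroni: bool = False,
) -> pd.DataFrame:
    """Per-chromosome one-cell chi-square test of observed vs expected counts.

    ``n`` defaults to the total observed count.  The statistic is
    ``(O - E)^2 / E`` with a two-sided df=1 p-value; chromosomes are flagged
    at ``alpha`` and ``alpha_strict`` (optionally Bonferroni-divided by the
    number of chromosomes tested).  Chromosomes with zero expectation are
    skipped with a warning.
    """
    if n is None:
        n = int(sum(observed.get(c, 0) for c in chrom_lengths))
    exp = expected_counts(chrom_lengths, n).set_index("chrom")
    k = len(chrom_lengths)
    a1 = alpha / k if bonferroni else alpha
    a2 = alpha_strict / k if bonferroni else alpha_strict
    rows = []
    for chrom in chrom_lengths:
        e = float(exp.loc[chrom, "expected"])
        o = int(observed.get(chrom, 0))
        if e == 0:
            logger.warning("chromosome %s has zero expected count; skipped", chrom)
            continue
        chi2 = (o - e) ** 2 / e
        p = float(stats.chi2.sf(chi2, df=1))
        rows.append(
            {
                "chrom": chrom,
                "length": int(chrom_lengths[chrom]),
                "observed": o,
                "expected": e,
                "expected_rounded": int(np.rint(e)),
                "chi_square": chi2,
                "p_value": p,
                "significant": p < a1,
                "significant_strict": p < a2,
                "direction": "enriched" if o > e else ("depleted" if o < e else "as_expected"),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# gene context
# ---------------------------------------------------------------------------

_ATTR_RE = re.compile(r'(\w+) "([^"]*)"')


def read_gtf_intervals(path: str | Path) -> pd.DataFrame:
    """Read gene and exon features from a Gencode-dialect GTF.

    Returns a frame with columns chrom, source_feature (gene|exon), start,
    end (0-based half-open), strand, gene_name.  Rows that fail to parse are
    skipped with a logged warning.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                logger.warning("malformed GTF row %d skipped", lineno)
                continue
            chrom, _, feature, start, end, _, strand, _, attrs = parts[:9]
            if feature not in ("gene", "exon"):
                continue
            try:
                start_i, end_i = int(start) - 1, int(end)
            except ValueError:
                logger.warning("malformed GTF row %d skipped", lineno)
                continue
            attr_map = dict(_ATTR_RE.findall(attrs))
            name = attr_map.get("gene_name") or attr_map.get("gene_id") or ""
            rows.append(
                {
                    "chrom": chrom, "feature": feature, "start": start_i,
                    "end": end_i, "strand": strand, "gene_name": name,
                }
            )
    return pd.DataFrame(rows, columns=["chrom", "feature", "start", "end", "strand", "gene_name"])


def read_bed12_intervals(path: str | Path) -> pd.DataFrame:
    """Read genes and exon blocks from BED12 into the same schema as the GTF reader."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            p = line.rstrip("\n").split("\t")
            chrom, start, end, name = p[0], int(p[1]), int(p[2]), p[3]
            strand = p[5] if len(p) > 5 else "+"
            rows.append(
                {"chrom": chrom, "feature": "gene", "start": start, "end": end,
                 "strand": strand, "gene_name": name}
            )
            if len(p) >= 12:
                sizes = [int(x) for x in p[10].rstrip(",").split(",")]
                offsets = [int(x) for x in p[11].rstrip(",").split(",")]
                for size, off in zip(sizes, offsets):
                    rows.append(
                        {"chrom": chrom, "feature": "exon", "start": start + off,
                         "end": start + off + size, "strand": strand, "gene_name": name}
                    )
    return pd.DataFrame(rows, columns=["chrom", "feature", "start", "end", "strand", "gene_name"])


@dataclass
class GeneContext:
    locus_name: str
    gene_name: str  # empty for intergenic
    gene_strand: str
    overlap_class: str  # intronic | exonic | intergenic
    orientation: str  # sense | antisense | "" for intergenic
    distance: int  # 0 when overlapping


def intersect_genes(
    loci: Sequence,
    annotation: pd.DataFrame,
) -> list[GeneContext]:
    """Classify each locus as intronic, exonic or intergenic.

    ``loci`` is a sequence of objects with name, chrom, start, end, strand
    (0-based half-open).  A locus overlapping a gene body but none of its
    exons is intronic; overlapping any exon is exonic; otherwise intergenic.
    When several genes overlap, the one with the largest overlap wins.
    Orientation is sense iff locus and gene strand agree.
    """
    gene_trees: dict[str, IntervalTree] = {}
    exon_lists: dict[str, list[tuple[int, int]]] = {}
    for _, row in annotation.iterrows():
        key = (row["chrom"], row["gene_name"], row["strand"])
        if row["feature"] == "gene":
            gene_trees.setdefault(row["chrom"], IntervalTree()).addi(
                row["start"], row["end"], (row["gene_name"], row["strand"])
            )
        elif row["feature"] == "exon":
            exon_lists.setdefault(row["gene_name"], []).append((row["start"], row["end"]))

    contexts = []
    for locus in loci:
        tree = gene_trees.get(locus.chrom)
        overlaps = sorted(
            tree.overlap(locus.start, locus.end) if tree else (),
            key=lambda iv: (
                -(min(iv.end, locus.end) - max(iv.begin, locus.start)),
                iv.data[0],
            ),
        )
        if not overlaps:
            contexts.append(
                GeneContext(locus.name, "", "", "intergenic", "", -1)
            )
            continue
        best = overlaps[0]
        gene_name, gene_strand = best.data
        exonic = any(
            max(s, locus.start) < min(e, locus.end)
            for s, e in exon_lists.get(gene_name, ())
        )
        contexts.append(
            GeneContext(
                locus_name=locus.name,
                gene_name=gene_name,
                gene_strand=gene_strand,
                overlap_class="exonic" if exonic else "intronic",
                orientation="sense" if locus.strand == gene_strand else "antisense",
                distance=0,
            )
        )
    return contexts


# ---------------------------------------------------------------------------
# centromere context
# ---------------------------------------------------------------------------


def read_cytoband(path: str | Path) -> pd.DataFrame:
    """Read a UCSC cytoBand table (chrom, start, end, band, gieStain)."""
    return pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "band", "stain"], comment="#",
    )


@dataclass
class CentromereContext:
    locus_name: str
    flag: str  # centromeric | pericentromeric | other


def flag_centromeric(
    loci: Sequence,
    cytobands: pd.DataFrame,
    pericentromeric_margin: int = 5_000_000,
) -> list[CentromereContext]:
    """Flag loci overlapping (centromeric) or near (pericentromeric) acen bands.

    Pericentromeric means within ``pericentromeric_margin`` bp of an acen
    boundary or inside the band immediately adjacent to acen.  Loci on
    chromosomes missing from the band table are flagged "other" with a
    logged warning.
    """
    acen = cytobands[cytobands["stain"] == "acen"]
    acen_span: dict[str, tuple[int, int]] = {}
    for chrom, grp in acen.groupby("chrom"):
        acen_span[chrom] = (int(grp["start"].min()), int(grp["end"].max()))
    adjacent: dict[str, list[tuple[int, int]]] = {}
    for chrom, (a_s, a_e) in acen_span.items():
        bands = cytobands[cytobands["chrom"] == chrom].sort_values("start")
        nonacen = bands[bands["stain"] != "acen"]
        before = nonacen[nonacen["end"] <= a_s]
        after = nonacen[nonacen["start"] >= a_e]
        adj = []
        if not before.empty:
            last = before.iloc[-1]
            adj.append((int(last["start"]), int(last["end"])))
        if not after.empty:
            first = after.iloc[0]
            adj.append((int(first["start"]), int(first["end"])))
        adjacent[chrom] = adj

    out = []
    for locus in loci:
        if locus.chrom not in acen_span:
            logger.warning("chromosome %s missing from cytoband table", locus.chrom)
            out.append(CentromereContext(locus.name, "other"))
            continue
        a_s, a_e = acen_span[locus.chrom]
        if max(a_s, locus.start) < min(a_e, locus.end):
            out.append(CentromereContext(locus.name, "centromeric"))
            continue
        near = (
            locus.end > a_s - pericentromeric_margin and locus.start < a_e + pericentromeric_margin
        )
        in_adjacent = any(
            max(s, locus.start) < min(e, locus.end) for s, e in adjacent[locus.chrom]
        )
        flag = "pericentromeric" if (near or in_adjacent) else "other"
        out.append(CentromereContext(locus.name, flag))
    return out


def read_chrom_lengths(path: str | Path) -> dict[str, int]:
    """Read a two-column (chrom, length) TSV, skipping comment lines."""
    out: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] in ("chrom", "chromosome"):
                continue
            out[parts[0]] = int(parts[1])
    return out
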