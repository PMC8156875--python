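"""Classification of candidate loci into proviruses, solitary LTRs and rejects.

The curation logic mirrors how HML7 elements were catalogued against the
group reference: candidates are extracted with 500-nt flanks, globally
aligned to the full proviral reference and to the LTR consensus feature,
elements under 90% identity are rejected, and candidates that match the LTR
but carry essentially none of the internal (gag..env) portion are called
solitary LTRs.

Genome-wide search is a provided-coordinates workflow (BED in); a naive
exact-k-mer seed-and-chain scanner is included for synthetic genomes, where
it recovers planted intervals exactly at zero age.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import Align

from .reference import ReferenceModel
from .synthetic_data import revcomp

DEFAULT_FLANK = 500
DEFAULT_MIN_IDENTITY = 90.0
DEFAULT_INTERNAL_COVERAGE_MAX = 0.05


def make_aligner(
    match: float = 2.0,
    mismatch: float = -3.0,
    open_gap: float = -5.0,
    extend_gap: float = -2.0,
    free_target_ends: bool = True,
    free_query_ends: bool = True,
    end_extend: float = 0.0,
) -> Align.PairwiseAligner:
    """Affine-gap global aligner; end gaps optionally cheap on either row.

    In Biopython terms the first sequence passed to ``align`` is the target
    and the second the query; "insertions" are gaps in the target row and
    "deletions" gaps in the query row.  ``end_extend`` is the per-base score
    of the relaxed end gaps: 0 makes them free (semi-global identity), a
    small negative value keeps truncations cheap while preventing the
    optimizer from trading an internal gap for a spurious end skip — a real
    failure mode when the target contains duplicated segments, as an
    LTR-bounded provirus does.
    """
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = open_gap
    aligner.extend_gap_score = extend_gap
    end_open = 0.0 if end_extend == 0.0 else open_gap
    if free_target_ends:
        # query overhangs beyond the target
        aligner.open_end_insertion_score = end_open
        aligner.extend_end_insertion_score = end_extend
    if free_query_ends:
        # target overhangs beyond the query
        aligner.open_end_deletion_score = end_open
        aligner.extend_end_deletion_score = end_extend
    return aligner


def _aligned_rows(alignment) -> tuple[str, str]:
    return str(alignment[0]), str(alignment[1])


def _trim_end_gap_columns(a: str, b: str) -> tuple[str, str]:
    """Drop terminal columns gapped in either row (end gaps)."""
    start, end = 0, len(a)
    while start < end and (a[start] == "-" or b[start] == "-"):
        start += 1
    while end > start and (a[end - 1] == "-" or b[end - 1] == "-"):
        end -= 1
    return a[start:end], b[start:end]


def percent_identity(query: str, subject: str, aligner: Align.PairwiseAligner | None = None) -> float:
    """Global-alignment percent identity, end-gap columns excluded.

    Identity is matches / aligned columns over the core of the alignment;
    internal gap columns count in the denominator, terminal gap runs do not.
    The two sequences are passed to the aligner in a canonical order so the
    metric is symmetric even when co-optimal alignments differ.
    """
    if not query or not subject:
        raise ValueError("percent_identity requires non-empty sequences")
    if aligner is None:
        aligner = make_aligner()
    first, second = sorted((subject.upper(), query.upper()))
    aln = aligner.align(first, second)[0]
    a, b = _trim_end_gap_columns(*_aligned_rows(aln))
    if not a:
        return 0.0
    matches = sum(1 for x, y in zip(a, b) if x == y and x != "-")
    return 100.0 * matches / len(a)


@dataclass
class Candidate:
    """A candidate locus extracted from a genome with its flanks."""

    chrom: str
    start: int  # 0-based half-open
    end: int
    strand: str
    sequence: str
    flank5: str
    flank3: str


@dataclass
class Classification:
    category: str  # "provirus" | "solo_ltr" | "reject"
    full_identity: float
    ltr_identity: float
    internal_coverage: float


@dataclass
class LocusRecord:
    """One catalogued HML7-like element."""

    name: str
    chrom: str
    start: int  # 0-based half-open internally
    end: int
    strand: str
    category: str
    sequence: str
    flank5: str
    flank3: str
    percent_identity_to_reference: float

    @property
    def interval_1based(self) -> tuple[int, int]:
        """1-based inclusive coordinates as used in report files."""
        return self.start + 1, self.end


def extract_with_flanks(
    genome: Mapping[str, str],
    chrom: str,
    start: int,
    end: int,
    strand: str = "+",
    flank_len: int = DEFAULT_FLANK,
) -> Candidate:
    """Extract a locus plus up to ``flank_len`` nt of flanking sequence.

    Coordinates are 0-based half-open on the forward strand.  For a minus
    strand locus, sequence and flanks are reverse-complemented and the 5'
    flank is the genomic right flank.
    """
    if chrom not in genome:
        raise KeyError(f"chromosome {chrom} not in genome")
    chrom_seq = genome[chrom]
    if not (0 <= start < end <= len(chrom_seq)):
        raise ValueError(f"interval [{start}, {end}) outside {chrom}")
    left = chrom_seq[max(0, start - flank_len) : start]
    core = chrom_seq[start:end]
    right = chrom_seq[end : min(len(chrom_seq), end + flank_len)]
    if strand == "-":
        core = revcomp(core)
        left, right = revcomp(right), revcomp(left)
    return Candidate(
        chrom=chrom, start=start, end=end, strand=strand,
        sequence=core, flank5=left, flank3=right,
    )


def _internal_coverage(reference: ReferenceModel, ref_aligned: str, qry_aligned: str) -> float:
    """Fraction of the internal (gag..env) span aligned to query bases."""
    s, e = reference.internal_span
    covered = 0
    ref_pos = 0
    for rc, qc in zip(ref_aligned, qry_aligned):
        if rc != "-":
            ref_pos += 1
            if s <= ref_pos <= e and qc != "-":
                covered += 1
    return covered / (e - s + 1)


def classify_candidate(
    candidate: Candidate | str,
    reference: ReferenceModel,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    internal_coverage_max: float = DEFAULT_INTERNAL_COVERAGE_MAX,
    aligner: Align.PairwiseAligner | None = None,
) -> Classification:
    """Call a candidate provirus, solitary LTR, or reject.

    Rejects when identity to both the full reference and the LTR feature is
    below ``min_identity``; calls a solitary LTR when LTR identity passes but
    the candidate covers less than ``internal_coverage_max`` of the internal
    gag..env span; otherwise calls a provirus.
    """
    seq = candidate.sequence if isinstance(candidate, Candidate) else str(candidate)
    if not seq:
        raise ValueError("empty candidate sequence")
    if aligner is None:
        aligner = make_aligner()
    ltr_identity = percent_identity(seq, reference.feature_sequence("LTR5"), aligner)
    aln = aligner.align(reference.sequence, seq.upper())[0]
    ra, qa = _aligned_rows(aln)
    ta, tb = _trim_end_gap_columns(ra, qa)
    matches = sum(1 for x, y in zip(ta, tb) if x == y and x != "-")
    full_identity = 100.0 * matches / len(ta) if ta else 0.0
    internal_cov = _internal_coverage(reference, ra, qa)
    if full_identity < min_identity and ltr_identity < min_identity:
        category = "reject"
    elif ltr_identity >= min_identity and internal_cov < internal_coverage_max:
        category = "solo_ltr"
    else:
        category = "provirus"
    return Classification(
        category=category,
        full_identity=full_identity,
        ltr_identity=ltr_identity,
        internal_coverage=internal_cov,
    )


# ---------------------------------------------------------------------------
# naive seed-and-chain scanner for synthetic genomes
# ---------------------------------------------------------------------------


def _kmer_index(seq: str, k: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        index.setdefault(seq[i : i + k], []).append(i)
    return index


def scan_genome(
    genome: Mapping[str, str],
    reference: ReferenceModel,
    k: int = 25,
    max_gap: int = 500,
    min_hits: int = 3,
    diagonal_tolerance: int = 30,
) -> list[tuple[str, int, int, str]]:
    """Locate reference-like intervals by exact k-mer seeding and chaining.

    Seeds are exact ``k``-mers shared with the reference (either strand),
    chained per alignment diagonal (seed position minus reference position);
    chains with fewer than ``min_hits`` seeds are discarded (this drops
    chance matches straddling element boundaries) and overlapping chains are
    merged (a provirus also seeds a duplicated-LTR diagonal).  At zero age
    every element position seeds, so planted intervals are recovered
    exactly.  Returns 0-based half-open ``(chrom, start, end, strand)``.
    """
    index = _kmer_index(reference.sequence.upper(), k)
    hits: list[tuple[str, int, int, str]] = []
    for chrom, seq in genome.items():
        seq = seq.upper()
        for strand, scan_seq in (("+", seq), ("-", revcomp(seq))):
            matches: list[tuple[int, int]] = []  # (diagonal, pos)
            for i in range(len(scan_seq) - k + 1):
                for ref_pos in index.get(scan_seq[i : i + k], ()):
                    matches.append((i - ref_pos, i))
            matches.sort()
            chains: list[list[tuple[int, int]]] = []
            for d, pos in matches:
                if (
                    chains
                    and abs(d - chains[-1][-1][0]) <= diagonal_tolerance
                    and pos - chains[-1][-1][1] <= max_gap
                ):
                    chains[-1].append((d, pos))
                else:
                    chains.append([(d, pos)])
            intervals = []
            for chain in chains:
                if len(chain) < min_hits:
                    continue
                s = min(p for _, p in chain)
                e = max(p for _, p in chain) + k
                intervals.append((s, e))
            # merge overlapping chains (duplicated-LTR diagonals)
            intervals.sort()
            merged: list[list[int]] = []
            for s, e in intervals:
                if merged and s < merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            for s, e in merged:
                if strand == "-":
                    s, e = len(seq) - e, len(seq) - s
                hits.append((chrom, s, e, strand))
    hits.sort()
    return hits


# ---------------------------------------------------------------------------
# catalog assembly and summary
# ---------------------------------------------------------------------------


def _band_name(cytobands, chrom: str, pos: int) -> str | None:
    if cytobands is None:
        return None
    sub = cytobands[(cytobands["chrom"] == chrom)]
    row = sub[(sub["start"] <= pos) & (pos < sub["end"])]
    if row.empty:
        return None
    return chrom.removeprefix("chr") + row.iloc[0]["band"]


def build_catalog(
    genome: Mapping[str, str],
    intervals: Iterable[tuple[str, int, int, str]],
    reference: ReferenceModel,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    internal_coverage_max: float = DEFAULT_INTERNAL_COVERAGE_MAX,
    flank_len: int = DEFAULT_FLANK,
    cytobands=None,
) -> list[LocusRecord]:
    """Classify candidate intervals and assemble the locus catalog.

    Rejected candidates are dropped.  Loci are named by cytogenetic band when
    a cytoband table is supplied, else ``chrom:start-end`` (1-based
    inclusive); duplicate band names get letter suffixes.
    """
    aligner = make_aligner()
    records: list[LocusRecord] = []
    seen_names: dict[str, int] = {}
    for chrom, start, end, strand in intervals:
        cand = extract_with_flanks(genome, chrom, start, end, strand, flank_len)
        cls = classify_candidate(
            cand, reference, min_identity, internal_coverage_max, aligner
        )
        if cls.category == "reject":
            continue
        name = _band_name(cytobands, chrom, (start + end) // 2)
        if name is None:
            name = f"{chrom}:{start + 1}-{end}"
        if name in seen_names:
            seen_names[name] += 1
            name = f"{name}{chr(ord('a') + seen_names[name] - 1)}"
        else:
            seen_names[name] = 1
        identity = (
            cls.ltr_identity if cls.category == "solo_ltr" else cls.full_identity
        )
        records.append(
            LocusRecord(
                name=name, chrom=chrom, start=start, end=end, strand=strand,
                category=cls.category, sequence=cand.sequence,
                flank5=cand.flank5, flank3=cand.flank3,
                percent_identity_to_reference=identity,
            )
        )
    return records


def catalog_summary(records: Sequence[LocusRecord]) -> dict:
    """Counts per category and chromosome plus the rounded solo:provirus ratio."""
    n_prov = sum(1 for r in records if r.category == "provirus")
    n_solo = sum(1 for r in records if r.category == "solo_ltr")
    per_chrom: dict[str, dict[str, int]] = {}
    for r in records:
        per_chrom.setdefault(r.chrom, {"provirus": 0, "solo_ltr": 0})
        per_chrom[r.chrom][r.category] += 1
    if n_prov == 0 or n_solo == 0:
        ratio = "-"
    else:
        ratio = f"1:{round(n_solo / n_prov)}"
    return {
        "n_provirus": n_prov,
        "n_solo_ltr": n_solo,
        "n_total": n_prov + n_solo,
        "per_chromosome": per_chrom,
        "solo_to_provirus_ratio": ratio,
    }


def write_catalog_tsv(records: Sequence[LocusRecord], path: str | Path) -> None:
    """Catalog TSV with 1-based inclusive coordinates (report convention)."""
    with open(path, "w") as fh:
        fh.write("name\tchrom\tstart\tend\tstrand\tcategory\tpercent_identity\n")
        for r in records:
            s1, e1 = r.interval_1based
            fh.write(
                f"{r.name}\t{r.chrom}\t{s1}\t{e1}\t{r.strand}\t{r.category}"
                f"\t{r.percent_identity_to_reference:.2f}\n"
            )


def write_catalog_fasta(records: Sequence[LocusRecord], path: str | Path, flanks: bool = False) -> None:
    with open(path, "w") as fh:
        for r in records:
            seq = r.flank5 + r.sequence + r.flank3 if flanks else r.sequence
            fh.write(f">{r.name}\n{seq}\n")


def read_candidates_bed(path: str | Path) -> list[tuple[str, int, int, str]]:
    """Read BED (>=3 columns; strand from column 6 when present)."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            p = line.rstrip("\n").split("\t")
            strand = p[5] if len(p) > 5 and p[5] in "+-" else "+"
            out.append((p[0], int(p[1]), int(p[2]), strand))
    return out
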