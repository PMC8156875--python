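"""Reference-anchored structural annotation of proviral loci.

Each provirus is globally aligned to the annotated group reference (affine
gaps: match 2, mismatch -3, open -5, extend -2; end gaps on the locus are
free, so 5'/3' truncations are not penalized).  From the anchored alignment
the module annotates insertions and deletions in reference coordinates,
clusters deletions recurring across loci, measures per-gene coverage and
structural completeness, and scans open reading frames for internal stop
codons, frameshifting indels, the Gag nucleocapsid CCHC zinc-knuckle motif,
and base composition.

Reading-frame boundary notation: the relative frame of consecutive genes is
reported in the retroviral {0, -1, +1} translation-strategy notation
(readthrough vs ribosomal frameshift).  The mapping from the observed
start-offset difference mod 3 is fixed so that the HML7 reference gene
layout reproduces the group's published "0/-1" gag-pro/pro-pol pattern:
offset 2 -> 0 (readthrough), offset 0 -> -1, offset 1 -> +1.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from Bio.Seq import Seq

from .locus_catalog import make_aligner, percent_identity
from .reference import ReferenceModel

#: start-offset difference (mod 3) -> ribosomal shift notation
SHIFT_NOTATION = {2: 0, 0: -1, 1: +1}

#: CCHC zinc-knuckle of the Gag nucleocapsid: C-X2-C-X4-H-X4-C
ZINC_FINGER_PATTERN = re.compile(r"C.{2}C.{4}H.{4}C")

GENE_FEATURES = ("gag", "pro", "pol", "env")


@dataclass
class AnchoredAlignment:
    """A locus aligned to the reference, with a column -> coordinate map."""

    locus_name: str
    ref_aligned: str
    qry_aligned: str

    def __post_init__(self) -> None:
        if len(self.ref_aligned) != len(self.qry_aligned):
            raise ValueError("aligned rows differ in length")

    def ref_positions(self) -> np.ndarray:
        """Per-column 1-based reference position (0 for insertion columns)."""
        pos = np.zeros(len(self.ref_aligned), dtype=int)
        p = 0
        for i, c in enumerate(self.ref_aligned):
            if c != "-":
                p += 1
                pos[i] = p
        return pos

    def query_base_at(self, ref_pos: int) -> str | None:
        """Query symbol aligned to a reference position, or None if unaligned."""
        positions = self.ref_positions()
        idx = np.nonzero(positions == ref_pos)[0]
        if idx.size == 0:
            return None
        c = self.qry_aligned[idx[0]]
        return None if c == "-" else c


@dataclass
class IndelAnnotation:
    """One insertion or deletion relative to the reference.

    Deletions carry the deleted 1-based inclusive reference interval;
    insertions are anchored after ``ref_start`` (= ``ref_end``) and carry the
    inserted query sequence.  ``terminal`` marks gap runs touching either
    alignment end (truncations rather than internal indels).
    """

    locus_name: str
    kind: str  # "insertion" | "deletion"
    ref_start: int
    ref_end: int
    length: int
    inserted_sequence: str = ""
    terminal: bool = False


def anchor_to_reference(
    locus_sequence: str,
    reference: ReferenceModel,
    locus_name: str = "locus",
    min_identity: float | None = None,
) -> AnchoredAlignment:
    """Globally align a locus to the reference with free locus end gaps."""
    if not locus_sequence:
        raise ValueError("empty locus sequence")
    aligner = make_aligner(free_target_ends=False, free_query_ends=True, end_extend=-0.1)
    if min_identity is not None:
        ident = percent_identity(locus_sequence, reference.sequence, make_aligner())
        if ident < min_identity:
            raise ValueError(
                f"{locus_name}: identity {ident:.1f}% below threshold {min_identity}%"
            )
    aln = aligner.align(reference.sequence, locus_sequence.upper())[0]
    return AnchoredAlignment(
        locus_name=locus_name, ref_aligned=str(aln[0]), qry_aligned=str(aln[1])
    )


def annotate_indels(anchored: AnchoredAlignment, normalize: bool = True) -> list[IndelAnnotation]:
    """Annotate maximal gap runs as indel events in reference coordinates.

    Adjacent runs separated by at least one aligned column are distinct
    events.  Terminal runs (alignment-end gaps) are flagged ``terminal``.
    With ``normalize`` (default), each event is shifted to its left-most
    equivalent placement — when the base before a deletion equals the base
    at its end, the two placements produce the same sequence and the
    aligner's choice between them is arbitrary.
    """
    ref, qry = anchored.ref_aligned, anchored.qry_aligned
    n = len(ref)
    events: list[IndelAnnotation] = []
    ref_pos = 0
    i = 0
    while i < n:
        if qry[i] == "-" and ref[i] != "-":
            start_ref = ref_pos + 1
            j = i
            while j < n and qry[j] == "-" and ref[j] != "-":
                ref_pos += 1
                j += 1
            events.append(
                IndelAnnotation(
                    locus_name=anchored.locus_name, kind="deletion",
                    ref_start=start_ref, ref_end=ref_pos,
                    length=ref_pos - start_ref + 1,
                    terminal=(i == 0 or j == n),
                )
            )
            i = j
        elif ref[i] == "-" and qry[i] != "-":
            j = i
            ins = []
            while j < n and ref[j] == "-" and qry[j] != "-":
                ins.append(qry[j])
                j += 1
            events.append(
                IndelAnnotation(
                    locus_name=anchored.locus_name, kind="insertion",
                    ref_start=ref_pos, ref_end=ref_pos,
                    length=len(ins), inserted_sequence="".join(ins),
                    terminal=(i == 0 or j == n),
                )
            )
            i = j
        else:
            if ref[i] != "-":
                ref_pos += 1
            i += 1
    if normalize:
        plain_ref = ref.replace("-", "")
        for ev in events:
            if ev.terminal:
                continue
            if ev.kind == "deletion":
                a, b = ev.ref_start, ev.ref_end
                while a > 1 and plain_ref[a - 2] == plain_ref[b - 1]:
                    a -= 1
                    b -= 1
                ev.ref_start, ev.ref_end = a, b
            else:
                p, ins = ev.ref_start, ev.inserted_sequence
                while p > 0 and ins and plain_ref[p - 1] == ins[-1]:
                    ins = ins[-1] + ins[:-1]
                    p -= 1
                ev.ref_start = ev.ref_end = p
                ev.inserted_sequence = ins
    return events


def apply_indels(reference_sequence: str, indels: Sequence[IndelAnnotation]) -> str:
    """Apply annotated indels to the reference (round-trip oracle).

    For an alignment without substitutions this reconstructs the query
    exactly; with substitutions it reconstructs the query's gap structure.
    """
    deletions = sorted(
        (iv for iv in indels if iv.kind == "deletion"), key=lambda iv: iv.ref_start
    )
    insertions = sorted(
        (iv for iv in indels if iv.kind == "insertion"), key=lambda iv: iv.ref_start
    )
    deleted = np.zeros(len(reference_sequence), dtype=bool)
    for d in deletions:
        deleted[d.ref_start - 1 : d.ref_end] = True
    ins_after: dict[int, str] = {}
    for ins in insertions:
        ins_after[ins.ref_start] = ins_after.get(ins.ref_start, "") + ins.inserted_sequence
    out = [ins_after.get(0, "")]
    for p, base in enumerate(reference_sequence, start=1):
        if not deleted[p - 1]:
            out.append(base)
        if p in ins_after and p != 0:
            out.append(ins_after[p])
    return "".join(out)


# ---------------------------------------------------------------------------
# recurrent deletions
# ---------------------------------------------------------------------------


def recurrent_deletions(
    indel_annotations: Sequence[IndelAnnotation],
    min_loci: int = 3,
    overlap_tolerance: float = 0.8,
    include_terminal: bool = False,
) -> list[dict]:
    """Cluster deletions shared across loci by reciprocal overlap.

    Two deletions cluster when their reciprocal overlap (overlap divided by
    each interval's length) is at least ``overlap_tolerance``; clusters are
    transitive closures.  Clusters supported by at least ``min_loci``
    distinct loci are reported with a consensus (median) interval.
    """
    dels = [
        d for d in indel_annotations
        if d.kind == "deletion" and (include_terminal or not d.terminal)
    ]
    if len({d.locus_name for d in dels}) < 2:
        return []
    parent = list(range(len(dels)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(len(dels)):
        for j in range(i + 1, len(dels)):
            a, b = dels[i], dels[j]
            ov = min(a.ref_end, b.ref_end) - max(a.ref_start, b.ref_start) + 1
            if ov <= 0:
                continue
            if ov / a.length >= overlap_tolerance and ov / b.length >= overlap_tolerance:
                parent[find(i)] = find(j)

    clusters: dict[int, list[IndelAnnotation]] = {}
    for i, d in enumerate(dels):
        clusters.setdefault(find(i), []).append(d)
    out = []
    for members in clusters.values():
        loci = sorted({m.locus_name for m in members})
        if len(loci) < min_loci:
            continue
        out.append(
            {
                "ref_start": int(np.median([m.ref_start for m in members])),
                "ref_end": int(np.median([m.ref_end for m in members])),
                "support": len(loci),
                "loci": loci,
            }
        )
    out.sort(key=lambda c: (-c["support"], c["ref_start"]))
    return out


# ---------------------------------------------------------------------------
# gene integrity
# ---------------------------------------------------------------------------


def feature_coverage(anchored: AnchoredAlignment, reference: ReferenceModel) -> dict[str, float]:
    """Fraction of each feature's reference positions aligned to query bases."""
    positions = anchored.ref_positions()
    aligned_ref = np.zeros(len(reference) + 1, dtype=bool)
    for i, p in enumerate(positions):
        if p and anchored.qry_aligned[i] != "-":
            aligned_ref[p] = True
    cov = {}
    for feat, (s, e) in reference.features.items():
        cov[feat] = float(aligned_ref[s : e + 1].mean())
    cov["overall"] = float(aligned_ref[1:].mean())
    return cov


def gene_integrity(
    anchored: AnchoredAlignment,
    reference: ReferenceModel,
    complete_threshold: float = 0.95,
    near_complete_threshold: float = 0.80,
    ltr_presence_threshold: float = 0.5,
) -> dict:
    """Per-feature coverage, LTR presence calls and structural class."""
    cov = feature_coverage(anchored, reference)
    overall = cov["overall"]
    if overall >= complete_threshold:
        structural_class = "complete"
    elif overall >= near_complete_threshold:
        structural_class = "near_complete"
    else:
        structural_class = "defective"
    return {
        "coverage": cov,
        "ltr5_present": cov["LTR5"] >= ltr_presence_threshold,
        "ltr3_present": cov["LTR3"] >= ltr_presence_threshold,
        "structural_class": structural_class,
    }


# ---------------------------------------------------------------------------
# ORF scanning
# ---------------------------------------------------------------------------


@dataclass
class GeneOrf:
    present_fraction: float
    frameshift_count: int | None
    internal_stop_count: int | None


@dataclass
class OrfReport:
    locus_name: str
    genes: dict[str, GeneOrf] = field(default_factory=dict)
    gag_pro_shift: int | None = None
    pro_pol_shift: int | None = None
    zinc_finger_hits: int = 0
    composition: dict[str, float] = field(default_factory=dict)


def composition(sequence: str) -> dict[str, float]:
    """Base fractions over unambiguous bases, plus AT% and GC%."""
    seq = sequence.upper()
    counts = {b: seq.count(b) for b in "ACGT"}
    total = sum(counts.values())
    if total == 0:
        raise ValueError("sequence contains no unambiguous bases")
    frac = {b: c / total for b, c in counts.items()}
    frac["AT_percent"] = 100.0 * (frac["A"] + frac["T"])
    frac["GC_percent"] = 100.0 * (frac["C"] + frac["G"])
    return frac


def zinc_finger_scan(sequence: str, is_protein: bool = False) -> tuple[int, list[int]]:
    """Count CCHC zinc-knuckle motifs (C-X2-C-X4-H-X4-C), non-overlapping.

    Nucleotide input is translated in frame 0 first.
    """
    if is_protein:
        peptide = sequence.upper()
    else:
        seq = sequence.upper()
        seq = seq[: len(seq) - len(seq) % 3]
        peptide = str(Seq(seq).translate())
    hits = [m.start() for m in ZINC_FINGER_PATTERN.finditer(peptide)]
    return len(hits), hits


def _query_index_at(anchored: AnchoredAlignment, ref_pos: int, search: int = 30) -> int | None:
    """0-based query index aligned at ``ref_pos``; frame-preserving fallback.

    If the exact position is unaligned, the nearest aligned reference
    position within ``search`` bp downstream is used and the query index is
    shifted back by the reference offset (exact when no indel intervenes).
    """
    positions = anchored.ref_positions()
    qidx = np.cumsum([c != "-" for c in anchored.qry_aligned]) - 1
    for offset in range(search + 1):
        target = ref_pos + offset
        cols = np.nonzero(positions == target)[0]
        if cols.size and anchored.qry_aligned[cols[0]] != "-":
            return int(qidx[cols[0]]) - offset
    return None


def _gene_query_sequence(anchored: AnchoredAlignment, start: int, end: int) -> str:
    """Query bases in columns spanning reference positions [start, end]."""
    positions = anchored.ref_positions()
    cols_in = np.nonzero((positions >= start) & (positions <= end))[0]
    if cols_in.size == 0:
        return ""
    lo, hi = cols_in[0], cols_in[-1]
    return anchored.qry_aligned[lo : hi + 1].replace("-", "")


def orf_scan(anchored: AnchoredAlignment, reference: ReferenceModel) -> OrfReport:
    """Stop-codon, frameshift, frame-boundary and motif statistics per gene.

    Each gene is translated in the reading frame fixed by its start on the
    reference; internal stops are stop codons strictly inside the gene,
    frameshifts are indel events within the gene whose length is not a
    multiple of 3.  Genes with under 5% coverage are reported absent
    (undefined counts).  Frame boundaries (gag-pro, pro-pol) are mapped to
    the {0, -1, +1} notation via :data:`SHIFT_NOTATION`.
    """
    cov = feature_coverage(anchored, reference)
    indels = annotate_indels(anchored)
    report = OrfReport(locus_name=anchored.locus_name)
    report.composition = composition(anchored.qry_aligned.replace("-", ""))

    for gene in GENE_FEATURES:
        if gene not in reference.features:
            continue
        s, e = reference.features[gene]
        frac = cov[gene]
        if frac < 0.05:
            report.genes[gene] = GeneOrf(frac, None, None)
            continue
        qseq = _gene_query_sequence(anchored, s, e)
        positions = anchored.ref_positions()
        covered = [
            int(p) for i, p in enumerate(positions)
            if p and s <= p <= e and anchored.qry_aligned[i] != "-"
        ]
        first_ref = covered[0] if covered else s
        frame_offset = (first_ref - s) % 3
        start_idx = (3 - frame_offset) % 3
        coding = qseq[start_idx:]
        coding = coding[: len(coding) - len(coding) % 3]
        peptide = str(Seq(coding).translate()) if coding else ""
        stops = peptide[:-1].count("*") if peptide else 0
        shifts = sum(
            1
            for iv in indels
            if not iv.terminal
            and iv.length % 3 != 0
            and (
                (iv.kind == "deletion" and iv.ref_start <= e and iv.ref_end >= s)
                or (iv.kind == "insertion" and s <= iv.ref_start < e)
            )
        )
        report.genes[gene] = GeneOrf(frac, shifts, stops)

    def boundary_shift(up: str, down: str) -> int | None:
        if report.genes.get(up) is None or report.genes.get(down) is None:
            return None
        if report.genes[up].frameshift_count is None or report.genes[down].frameshift_count is None:
            return None
        q_up = _query_index_at(anchored, reference.features[up][0])
        q_down = _query_index_at(anchored, reference.features[down][0])
        if q_up is None or q_down is None:
            return None
        return SHIFT_NOTATION[(q_down - q_up) % 3]

    report.gag_pro_shift = boundary_shift("gag", "pro")
    report.pro_pol_shift = boundary_shift("pro", "pol")

    gag = report.genes.get("gag")
    if gag is not None and gag.internal_stop_count is not None:
        s, e = reference.features["gag"]
        qseq = _gene_query_sequence(anchored, s, e)
        n_hits, _ = zinc_finger_scan(qseq)
        report.zinc_finger_hits = n_hits
    return report


# ---------------------------------------------------------------------------
# projection to a reference-coordinate MSA
# ---------------------------------------------------------------------------


def project_to_reference_msa(
    anchored_list: Sequence[AnchoredAlignment],
    reference: ReferenceModel,
    include_reference: bool = True,
) -> dict[str, str]:
    """Project anchored alignments onto reference columns (insertions dropped).

    Produces a pseudo-MSA of equal-length rows, one column per reference
    position, suitable for distance and consensus computation.
    """
    msa: dict[str, str] = {}
    if include_reference:
        msa[reference.name] = reference.sequence
    for anc in anchored_list:
        row = ["-"] * len(reference)
        positions = anc.ref_positions()
        for i, p in enumerate(positions):
            if p and anc.qry_aligned[i] != "-":
                row[p - 1] = anc.qry_aligned[i]
        msa[anc.locus_name] = "".join(row)
    return msa
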