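"""Synthetic genomes and evolved proviral loci with known ground truth.

Every downstream stage (cataloguing, distribution statistics, structural
annotation, phylogenetics, age estimation) is exercised against data produced
here, because no machine-readable sequence set is deposited for the HML7
group.  The simulator emulates the biology the analysis rests on:

* an ancestral provirus with byte-identical LTRs and an AT-biased base
  composition (~60% A+T, as reported for HERV-K internal sequences);
* neutral substitution at the human genomic clock rate (0.2%/nt/My by
  default), with hypermutable CpG dinucleotides (rate multiplier, default
  10x) and a transition bias (ts/tv ratio, default 2);
* lineage-specific deletions applied as discrete reference intervals;
* solitary-LTR formation by recombination between the two LTRs of one
  provirus, leaving a single chimeric LTR;
* ortholog presence in a primate species panel determined by integration age
  versus speciation time, with an optional loss probability.

Substitutions follow a single-draw model: each site differs from its
ancestral state with probability ``1 - exp(-rate * age * m)`` where ``m`` is
the CpG multiplier for sites inside an ancestral CpG, and mutated sites are
assigned one of the three alternative bases with the configured transition
bias.  Indels are not introduced by the substitution process; deletions are
explicit configured events.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from Bio.Seq import Seq

from .reference import HML7_FEATURES, ReferenceModel

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    """Reverse complement (delegates to Biopython)."""
    return str(Seq(seq).reverse_complement())


@dataclass
class SimulationConfig:
    """Parameters of a synthetic HML7 cohort.

    ``substitution_rate`` is per nucleotide per million years;
    ``locus_ages`` (My) sets one locus per entry; ``solo_fraction`` of the
    loci are converted to solitary LTRs (exact count, random subset);
    ``deletion_events`` are ``((start, end), probability)`` pairs with
    1-based inclusive reference intervals applied independently per provirus.
    """

    substitution_rate: float = 0.002
    cpg_multiplier: float = 10.0
    ts_tv_ratio: float = 2.0
    locus_ages: Sequence[float] = field(default_factory=list)
    solo_fraction: float = 0.0
    deletion_events: Sequence[tuple[tuple[int, int], float]] = field(
        default_factory=list
    )
    chromosome_lengths: Mapping[str, int] = field(default_factory=dict)
    target_at_fraction: float = 0.60
    ancestral_cpg_depletion: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.substitution_rate <= 0:
            raise ValueError("substitution_rate must be > 0")
        if any(a < 0 for a in self.locus_ages):
            raise ValueError("locus ages must be >= 0")
        if not 0.0 <= self.solo_fraction <= 1.0:
            raise ValueError("solo_fraction must be in [0, 1]")
        if self.cpg_multiplier < 1:
            raise ValueError("cpg_multiplier must be >= 1")


@dataclass
class TruthRecord:
    """Ground truth for one planted element."""

    locus_name: str
    true_age: float
    category: str  # "provirus" | "solo_ltr"
    chrom: str
    start: int  # 0-based half-open
    end: int
    strand: str
    deletions_applied: list[tuple[int, int]] = field(default_factory=list)
    species_present: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# sequence generation and evolution
# ---------------------------------------------------------------------------


def random_sequence(
    length: int,
    rng: np.random.Generator,
    at_fraction: float = 0.5,
    cpg_depletion: float = 1.0,
) -> str:
    """Random nucleotide sequence with the given expected A+T fraction.

    ``cpg_depletion`` scales the probability of a G following a C
    (first-order Markov draw, renormalized), emulating the CpG
    observed/expected ratio of genomic sequence; 1.0 means independent
    draws.  Depletion barely moves the overall composition because CpG
    pairs are rare.
    """
    p_at = at_fraction / 2.0
    p_gc = (1.0 - at_fraction) / 2.0
    p = np.array([p_at, p_gc, p_gc, p_at])
    if cpg_depletion >= 1.0:
        arr = rng.choice(_BASES, size=length, p=p)
        return arr.tobytes().decode("ascii")
    if cpg_depletion < 0:
        raise ValueError("cpg_depletion must be >= 0")

    # calibrate the base distribution so the chain's stationary AT fraction
    # hits the target despite the renormalization after C
    at_in = at_fraction
    for _ in range(30):
        p = np.array([at_in / 2, (1 - at_in) / 2, (1 - at_in) / 2, at_in / 2])
        p_after_c = p * np.array([1.0, 1.0, cpg_depletion, 1.0])
        p_after_c /= p_after_c.sum()
        pi_c = p[1] / (1.0 - p_after_c[1] + p[1])
        pi = pi_c * p_after_c + (1.0 - pi_c) * p
        at_in += at_fraction - (pi[0] + pi[3])
    p = np.array([at_in / 2, (1 - at_in) / 2, (1 - at_in) / 2, at_in / 2])
    p_after_c = p * np.array([1.0, 1.0, cpg_depletion, 1.0])
    p_after_c /= p_after_c.sum()
    # draw in two streams and pick per-position depending on the previous base
    draws_iid = rng.choice(4, size=length, p=p)
    draws_dep = rng.choice(4, size=length, p=p_after_c)
    out = np.empty(length, dtype=np.uint8)
    prev_c = False
    c_code = 1  # index of C in ACGT
    for i in range(length):
        b = draws_dep[i] if prev_c else draws_iid[i]
        out[i] = _BASES[b]
        prev_c = b == c_code
    return out.tobytes().decode("ascii")


def build_ancestral_provirus(
    reference: ReferenceModel | None = None,
    target_at_fraction: float = 0.60,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    cpg_depletion: float = 0.25,
) -> ReferenceModel:
    """Generate an ancestral provirus with byte-identical LTRs.

    If ``reference`` is given, only its length and feature layout are reused;
    the sequence is generated fresh.  The 5' LTR is generated once and copied
    onto the 3' LTR interval, so the two LTRs are identical as they are at
    the moment of integration.  The sequence is AT-biased and CpG-depleted
    (default observed/expected 0.25), as genomic and endogenous-retroviral
    sequence is: methylated CpGs decay fast, which is also why catalogued
    elements tens of My old still align at >=90% identity.
    """
    if not 0.0 < target_at_fraction < 1.0:
        raise ValueError("target_at_fraction must be in (0, 1)")
    if rng is None:
        rng = np.random.default_rng(seed)
    features = dict(reference.features) if reference is not None else dict(HML7_FEATURES)
    length = len(reference) if reference is not None else max(e for _, e in features.values())
    seq = np.frombuffer(
        random_sequence(length, rng, target_at_fraction, cpg_depletion).encode("ascii"),
        dtype=np.uint8,
    ).copy()
    l5s, l5e = features["LTR5"]
    l3s, l3e = features["LTR3"]
    seq[l3s - 1 : l3e] = seq[l5s - 1 : l5e]
    return ReferenceModel(
        sequence=seq.tobytes().decode("ascii"),
        features=features,
        name="HML7_ancestor",
    )


def _cpg_mask(codes: np.ndarray) -> np.ndarray:
    """Boolean mask of positions inside a CpG dinucleotide (C followed by G)."""
    is_c = codes == ord("C")
    is_g = codes == ord("G")
    cpg_start = is_c[:-1] & is_g[1:]
    mask = np.zeros(codes.shape, dtype=bool)
    mask[:-1] |= cpg_start
    mask[1:] |= cpg_start
    return mask


def evolve_sequence(
    seq: str,
    age: float,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> str:
    """Mutate ``seq`` for ``age`` million years under the configured clock.

    Each site differs from its input state with probability
    ``1 - exp(-rate * age * m)``; ``m`` is ``cpg_multiplier`` for sites inside
    a CpG of the input sequence.  Mutated sites transition (A<->G, C<->T)
    with probability ``ts_tv_ratio / (ts_tv_ratio + 1)``, else take one of
    the two transversions uniformly.  Length is preserved; non-ACGT symbols
    are left untouched.
    """
    if age < 0:
        raise ValueError("age must be >= 0")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if age == 0:
        return seq
    codes = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    acgt = np.isin(codes, _BASES)
    rate = config.substitution_rate * age
    m = np.where(_cpg_mask(codes), config.cpg_multiplier, 1.0)
    p_mut = 1.0 - np.exp(-rate * m)
    hit = (rng.random(codes.size) < p_mut) & acgt

    # map byte codes to 0..3 (A,C,G,T); transition partner is (b+2) mod 4
    lut = np.zeros(256, dtype=np.uint8)
    for i, b in enumerate(_BASES):
        lut[b] = i
    b = lut[codes[hit]]
    k = config.ts_tv_ratio
    is_ts = rng.random(b.size) < k / (k + 1.0)
    tv_pick = rng.integers(0, 2, size=b.size)
    new = np.where(is_ts, (b + 2) % 4, np.where(tv_pick == 0, (b + 1) % 4, (b + 3) % 4))
    codes[hit] = _BASES[new]
    return codes.tobytes().decode("ascii")


def make_solo_ltr(
    provirus: str,
    features: Mapping[str, tuple[int, int]],
    rng: np.random.Generator | None = None,
    breakpoint: int | None = None,
) -> str:
    """Recombine the two LTRs of a provirus into one solitary LTR.

    The product is the prefix of the 5' LTR up to ``breakpoint`` joined to
    the suffix of the 3' LTR from ``breakpoint`` (uniform breakpoint by
    default), modelling the homologous recombination that deletes the
    internal portion.  ``breakpoint=0`` returns the 3' copy unchanged.
    """
    for ltr in ("LTR5", "LTR3"):
        if ltr not in features:
            raise ValueError(f"provirus annotation lacks {ltr}")
    l5s, l5e = features["LTR5"]
    l3s, l3e = features["LTR3"]
    ltr5 = provirus[l5s - 1 : l5e]
    ltr3 = provirus[l3s - 1 : l3e]
    if len(ltr5) != len(ltr3):
        raise ValueError("LTR copies differ in length")
    if breakpoint is None:
        if rng is None:
            rng = np.random.default_rng()
        breakpoint = int(rng.integers(0, len(ltr5) + 1))
    if not 0 <= breakpoint <= len(ltr5):
        raise ValueError("breakpoint outside LTR")
    return ltr5[:breakpoint] + ltr3[breakpoint:]


def apply_deletions(seq: str, intervals: Sequence[tuple[int, int]]) -> str:
    """Remove 1-based inclusive intervals from ``seq`` (merged, right-to-left)."""
    keep = np.ones(len(seq), dtype=bool)
    for s, e in intervals:
        keep[s - 1 : e] = False
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return arr[keep].tobytes().decode("ascii")


# ---------------------------------------------------------------------------
# genome planting
# ---------------------------------------------------------------------------


def sample_placement_counts(
    chromosome_lengths: Mapping[str, int], n: int, rng: np.random.Generator
) -> dict[str, int]:
    """Assign ``n`` integrations to chromosomes, multinomially by length.

    This is the chromosome-assignment step of :func:`plant_loci`, exposed so
    the null (uniform-by-length) placement distribution can be sampled
    without generating sequence.
    """
    chroms = list(chromosome_lengths)
    lengths = np.array([chromosome_lengths[c] for c in chroms], dtype=float)
    counts = rng.multinomial(n, lengths / lengths.sum())
    return dict(zip(chroms, (int(c) for c in counts)))


def plant_loci(
    config: SimulationConfig,
    reference: ReferenceModel | None = None,
    max_retries: int = 200,
) -> tuple[dict[str, str], list[TruthRecord], ReferenceModel]:
    """Plant evolved proviruses and solitary LTRs into a random genome.

    Returns the genome (chromosome name -> sequence), the truth records
    (0-based half-open coordinates), and the ancestral reference used.
    Same seed, same inputs => bit-identical outputs.
    """
    if not config.chromosome_lengths:
        raise ValueError("config.chromosome_lengths is empty")
    rng = np.random.default_rng(config.seed)
    if reference is None:
        reference = build_ancestral_provirus(
            target_at_fraction=config.target_at_fraction,
            rng=rng,
            cpg_depletion=config.ancestral_cpg_depletion,
        )
    n = len(config.locus_ages)
    n_solo = int(round(config.solo_fraction * n))
    solo_idx = set(rng.choice(n, size=n_solo, replace=False).tolist()) if n_solo else set()

    counts = sample_placement_counts(config.chromosome_lengths, n, rng)
    order: list[str] = []
    for chrom in config.chromosome_lengths:
        order.extend([chrom] * counts[chrom])

    # build element sequences first so total length can be checked per chromosome
    elements: list[tuple[str, str, float, list[tuple[int, int]]]] = []
    for i, age in enumerate(config.locus_ages):
        evolved = evolve_sequence(reference.sequence, age, config, rng)
        if i in solo_idx:
            seq = make_solo_ltr(evolved, reference.features, rng)
            elements.append(("solo_ltr", seq, age, []))
        else:
            dels: list[tuple[int, int]] = []
            for interval, prob in config.deletion_events:
                if rng.random() < prob:
                    dels.append(tuple(interval))
            seq = apply_deletions(evolved, dels) if dels else evolved
            elements.append(("provirus", seq, age, dels))

    placements: dict[str, list[tuple[int, int]]] = {c: [] for c in config.chromosome_lengths}
    records: list[TruthRecord] = []
    for i, ((category, seq, age, dels), chrom) in enumerate(zip(elements, order)):
        clen = config.chromosome_lengths[chrom]
        if len(seq) >= clen:
            raise ValueError(f"element longer than chromosome {chrom}")
        placed = None
        for _ in range(max_retries):
            start = int(rng.integers(0, clen - len(seq) + 1))
            end = start + len(seq)
            if all(end <= s or start >= e for s, e in placements[chrom]):
                placed = (start, end)
                break
        if placed is None:
            raise RuntimeError(f"could not place element on {chrom} without overlap")
        placements[chrom].append(placed)
        strand = "+" if rng.random() < 0.5 else "-"
        records.append(
            TruthRecord(
                locus_name=f"locus_{i:03d}",
                true_age=float(age),
                category=category,
                chrom=chrom,
                start=placed[0],
                end=placed[1],
                strand=strand,
                deletions_applied=dels,
            )
        )

    genome: dict[str, str] = {}
    for chrom, clen in config.chromosome_lengths.items():
        arr = np.frombuffer(
            random_sequence(clen, rng, 0.5).encode("ascii"), dtype=np.uint8
        ).copy()
        genome[chrom] = arr
    for rec, (category, seq, age, dels) in zip(records, elements):
        planted = revcomp(seq) if rec.strand == "-" else seq
        genome[rec.chrom][rec.start : rec.end] = np.frombuffer(
            planted.encode("ascii"), dtype=np.uint8
        )
    # boundary guard: the background base adjacent to an element must not
    # continue the reference context (the LTR is a sub-span of the reference,
    # so a chance-matching neighbour would make the element boundary
    # genuinely ambiguous); real integration boundaries are not reference
    # continuations.
    l5_end = reference.features["LTR5"][1]
    l3_start = reference.features["LTR3"][0]
    after_ltr5 = reference.sequence[l5_end] if l5_end < len(reference) else ""
    before_ltr3 = reference.sequence[l3_start - 2] if l3_start >= 2 else ""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    for rec in records:
        if rec.strand == "+":
            left_forbidden = {before_ltr3}
            right_forbidden = {after_ltr5}
        else:
            left_forbidden = {comp.get(after_ltr5, "")}
            right_forbidden = {comp.get(before_ltr3, "")}
        arr = genome[rec.chrom]
        for pos, forbidden in ((rec.start - 1, left_forbidden), (rec.end, right_forbidden)):
            if 0 <= pos < arr.size and chr(arr[pos]) in forbidden:
                allowed = [b for b in "ACGT" if b not in forbidden]
                arr[pos] = ord(allowed[int(rng.integers(0, len(allowed)))])
    genome_str = {c: a.tobytes().decode("ascii") for c, a in genome.items()}
    return genome_str, records, reference


# ---------------------------------------------------------------------------
# ortholog presence/absence
# ---------------------------------------------------------------------------


def simulate_ortholog_matrix(
    records: Sequence[TruthRecord],
    species_panel: Mapping[str, float],
    loss_probability: float = 0.0,
    rng: np.random.Generator | None = None,
):
    """Presence/absence of each locus across a primate species panel.

    A locus is present in a species iff that species' divergence time from
    human is <= the locus's integration age; presences may be flipped to
    absent with ``loss_probability`` (modelling loci lost, e.g. converted to
    a solitary LTR, during speciation).  Human is always present.
    Records' ``species_present`` lists are filled in place.
    """
    import pandas as pd

    if rng is None:
        rng = np.random.default_rng()
    species = sorted(species_panel, key=lambda s: species_panel[s])
    data = {}
    for rec in records:
        row = {"human": True}
        for s in species:
            present = species_panel[s] <= rec.true_age
            if present and loss_probability > 0 and rng.random() < loss_probability:
                present = False
            row[s] = present
        rec.species_present = [s for s, v in row.items() if v]
        data[rec.locus_name] = row
    return pd.DataFrame.from_dict(data, orient="index", columns=["human"] + species)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def write_genome_fasta(genome: Mapping[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_truth_bed(records: Sequence[TruthRecord], path: str | Path) -> None:
    """BED6 of planted intervals (0-based half-open; score column unused)."""
    with open(path, "w") as fh:
        for r in records:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.locus_name}\t0\t{r.strand}\n")


def write_truth_tsv(records: Sequence[TruthRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "locus_name\ttrue_age\tcategory\tchrom\tstart\tend\tstrand"
            "\tdeletions_applied\tspecies_present\n"
        )
        for r in records:
            dels = ";".join(f"{s}-{e}" for s, e in r.deletions_applied)
            fh.write(
                f"{r.locus_name}\t{r.true_age}\t{r.category}\t{r.chrom}\t{r.start}"
                f"\t{r.end}\t{r.strand}\t{dels}\t{','.join(r.species_present)}\n"
            )


def read_truth_tsv(path: str | Path) -> list[TruthRecord]:
    records = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {c: i for i, c in enumerate(header)}
        for line in fh:
            p = line.rstrip("\n").split("\t")
            dels = [
                tuple(int(x) for x in d.split("-"))
                for d in p[idx["deletions_applied"]].split(";")
                if d
            ]
            records.append(
                TruthRecord(
                    locus_name=p[idx["locus_name"]],
                    true_age=float(p[idx["true_age"]]),
                    category=p[idx["category"]],
                    chrom=p[idx["chrom"]],
                    start=int(p[idx["start"]]),
                    end=int(p[idx["end"]]),
                    strand=p[idx["strand"]],
                    deletions_applied=dels,
                    species_present=[
                        s for s in p[idx["species_present"]].split(",") if s
                    ],
                )
            )
    return records
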