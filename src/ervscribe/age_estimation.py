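"""Multi-component molecular-clock dating of proviral integrations.

Each locus age is estimated as T = D / r, where D is the proportion of
divergent nucleotides and r the neutral substitution rate of the host genome
(default 0.002 per nucleotide per My).  Divergence is measured for several
components: each LTR and each gene region against the group consensus (which
stands in for the ancestral sequence), plus the divergence between the two
LTRs of the same provirus halved (the LTRs are identical at integration and
diverge independently afterwards).  Sites in a CpG dinucleotide of either
compared sequence are excluded (CpG hypermutation violates the clock), and
gapped sites are excluded pairwise.  Component estimates are averaged after
iteratively trimming outliers until the relative standard deviation drops
to the threshold (default 20%); loci whose estimates never stabilize are
flagged unreliable and their age withheld.

Comparative genomics cross-check: the oldest common ancestor (OCA) is the
most distantly diverged species carrying the orthologous integration; its
divergence time bounds the insertion age from below, the next older
speciation bounds it from above.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .reference import ReferenceModel

DEFAULT_RATE = 0.002  # substitutions / nucleotide / My
DEFAULT_SD_THRESHOLD = 0.20
DEFAULT_MIN_COVERAGE = 0.5

#: documented tie order for consensus calls
CONSENSUS_TIE_ORDER = "ACGT-"


def build_consensus(msa: Mapping[str, str] | Sequence[str], tie_order: str = CONSENSUS_TIE_ORDER) -> str:
    """Per-column majority consensus; gap counts as a state.

    Ties resolve by the fixed symbol order ``tie_order`` (A < C < G < T < gap).
    """
    rows = list(msa.values()) if isinstance(msa, Mapping) else list(msa)
    if len(rows) < 2:
        raise ValueError("consensus requires at least 2 sequences")
    if len({len(r) for r in rows}) != 1:
        raise ValueError("alignment rows have unequal lengths")
    rank = {c: i for i, c in enumerate(tie_order)}
    out = []
    for col in zip(*[r.upper() for r in rows]):
        counts: dict[str, int] = {}
        for c in col:
            counts[c] = counts.get(c, 0) + 1
        best = min(counts, key=lambda c: (-counts[c], rank.get(c, len(rank))))
        out.append(best)
    return "".join(out)


def _cpg_columns(aligned: str) -> set[int]:
    """Columns participating in a CpG dinucleotide of one aligned sequence.

    A CpG is a C whose next non-gap residue is G; both columns are marked.
    """
    cols: set[int] = set()
    prev_base, prev_col = None, -1
    for i, c in enumerate(aligned.upper()):
        if c == "-":
            continue
        if prev_base == "C" and c == "G":
            cols.add(prev_col)
            cols.add(i)
        prev_base, prev_col = c, i
    return cols


def divergence(
    a: str,
    b: str,
    exclude_cpg: bool = True,
    cpg_reference: str | Sequence[str] | None = None,
) -> float:
    """Proportion of differing sites between two aligned sequences.

    Pairwise deletion: columns gapped (or ambiguous) in either sequence are
    excluded.  With ``exclude_cpg``, columns inside a CpG dinucleotide are
    excluded as well.  By default a CpG observed in *either* compared
    sequence masks its columns; when ``cpg_reference`` supplies one or more
    aligned reference rows (e.g. the group consensus standing in for the
    ancestral state), CpGs are read from those rows only.  The reference
    form avoids a downward bias: substitutions create new CpGs next to
    existing C/G neighbours, so the either-sequence rule preferentially
    discards mutated sites.
    """
    if len(a) != len(b):
        raise ValueError("sequences must be aligned (equal length)")
    a, b = a.upper(), b.upper()
    if not exclude_cpg:
        skip: set[int] = set()
    elif cpg_reference is not None:
        refs = [cpg_reference] if isinstance(cpg_reference, str) else list(cpg_reference)
        skip = set()
        for ref in refs:
            if len(ref) != len(a):
                raise ValueError("cpg_reference must be aligned with the pair")
            skip |= _cpg_columns(ref)
    else:
        skip = _cpg_columns(a) | _cpg_columns(b)
    compared = 0
    mismatches = 0
    for i, (x, y) in enumerate(zip(a, b)):
        if x not in "ACGT" or y not in "ACGT" or i in skip:
            continue
        compared += 1
        if x != y:
            mismatches += 1
    if compared == 0:
        raise ValueError("no comparable sites")
    return mismatches / compared


def age_from_divergence(D: float, rate: float = DEFAULT_RATE) -> float:
    """T = D / rate (My)."""
    if D < 0:
        raise ValueError("divergence must be >= 0")
    if rate <= 0:
        raise ValueError("rate must be > 0")
    return D / rate


def ltr_pair_age(
    ltr5: str,
    ltr3: str,
    rate: float = DEFAULT_RATE,
    exclude_cpg: bool = True,
    cpg_reference: str | Sequence[str] | None = None,
) -> float:
    """Age from the divergence between a provirus's two LTRs, halved.

    The two LTRs are identical at integration and each accumulates
    substitutions independently, so the pairwise divergence corresponds to
    twice the age.  Unequal-length inputs are pairwise aligned first (in
    which case ``cpg_reference`` is not applicable).
    """
    if not ltr5 or not ltr3:
        raise ValueError("both LTRs are required")
    if len(ltr5) != len(ltr3):
        from .locus_catalog import make_aligner

        aln = make_aligner(free_target_ends=False, free_query_ends=False).align(
            ltr5.upper(), ltr3.upper()
        )[0]
        ltr5, ltr3 = str(aln[0]), str(aln[1])
        cpg_reference = None
    return (
        age_from_divergence(divergence(ltr5, ltr3, exclude_cpg, cpg_reference), rate)
        / 2.0
    )


@dataclass
class AgeReport:
    """Per-locus component estimates, trimming decisions and final age."""

    locus_name: str
    components: dict[str, float] = field(default_factory=dict)
    excluded: list[tuple[str, str]] = field(default_factory=list)  # (component, reason)
    mean_age: float | None = None
    relative_sd: float | None = None
    reliable: bool = True
    oca_species: str | None = None
    oca_window: tuple[float, float] | None = None
    consistent: str | None = None


def aggregate_age(
    components: Mapping[str, float],
    sd_threshold: float = DEFAULT_SD_THRESHOLD,
    locus_name: str = "locus",
) -> AgeReport:
    """Average component ages with iterative relative-SD trimming.

    While the relative standard deviation (sample SD / mean) exceeds
    ``sd_threshold`` and more than two components remain, the component
    farthest from the median is dropped.  If the criterion still fails with
    two components the locus is flagged unreliable and the age withheld.
    A single component is reported as-is (SD undefined).
    """
    if not components:
        raise ValueError("at least one component estimate required")
    report = AgeReport(locus_name=locus_name, components=dict(components))
    kept = dict(components)
    if len(kept) == 1:
        report.mean_age = float(next(iter(kept.values())))
        report.relative_sd = None
        return report

    def rel_sd(values: list[float]) -> float:
        mean = float(np.mean(values))
        if mean == 0:
            return 0.0
        return float(np.std(values, ddof=1)) / mean

    while True:
        values = list(kept.values())
        r = rel_sd(values)
        if r <= sd_threshold:
            report.mean_age = float(np.mean(values))
            report.relative_sd = r
            return report
        if len(kept) <= 2:
            report.mean_age = None
            report.relative_sd = r
            report.reliable = False
            return report
        median = float(np.median(values))
        drop = max(
            kept, key=lambda k: (abs(kept[k] - median), kept[k], k)
        )
        report.excluded.append((drop, f"relative SD {r:.2f} > {sd_threshold:.2f}"))
        del kept[drop]


# ---------------------------------------------------------------------------
# cohort-level estimation over a reference-coordinate MSA
# ---------------------------------------------------------------------------

#: component name -> features whose span is compared against the consensus
COMPONENT_REGIONS = {
    "ltr5_vs_consensus": ("LTR5",),
    "gag_pro_vs_consensus": ("gag", "pro"),
    "pol_vs_consensus": ("pol",),
    "env_vs_consensus": ("env",),
    "ltr3_vs_consensus": ("LTR3",),
}


def _region_slice(reference: ReferenceModel, features: Sequence[str]) -> slice:
    start = min(reference.features[f][0] for f in features)
    end = max(reference.features[f][1] for f in features)
    return slice(start - 1, end)


def estimate_ages(
    msa: Mapping[str, str],
    reference: ReferenceModel,
    rate: float = DEFAULT_RATE,
    sd_threshold: float = DEFAULT_SD_THRESHOLD,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
    exclude_from_consensus: Sequence[str] = (),
) -> dict[str, AgeReport]:
    """Estimate integration ages for every member of a group alignment.

    ``msa`` maps locus name to a row in reference coordinates (one column
    per reference position; see ``project_to_reference_msa``).  The group
    consensus is built from all member rows (optionally excluding, e.g.,
    the reference row itself).  Components with region coverage below
    ``min_coverage`` are skipped a priori; the LTR-pair component requires
    both LTRs.
    """
    members = {k: v for k, v in msa.items() if k not in set(exclude_from_consensus)}
    consensus = build_consensus(members)
    reports: dict[str, AgeReport] = {}
    for name, row in members.items():
        components: dict[str, float] = {}
        skipped: list[tuple[str, str]] = []
        for comp, feats in COMPONENT_REGIONS.items():
            sl = _region_slice(reference, feats)
            seg, cons_seg = row[sl], consensus[sl]
            coverage = sum(1 for c in seg if c != "-") / len(seg)
            if coverage < min_coverage:
                skipped.append((comp, f"coverage {coverage:.2f} < {min_coverage}"))
                continue
            try:
                D = divergence(seg, cons_seg, exclude_cpg=True, cpg_reference=cons_seg)
            except ValueError:
                skipped.append((comp, "no comparable sites"))
                continue
            components[comp] = age_from_divergence(D, rate)
        l5, l3 = _region_slice(reference, ("LTR5",)), _region_slice(reference, ("LTR3",))
        cov5 = sum(1 for c in row[l5] if c != "-") / (l5.stop - l5.start)
        cov3 = sum(1 for c in row[l3] if c != "-") / (l3.stop - l3.start)
        if cov5 >= min_coverage and cov3 >= min_coverage:
            try:
                components["ltr_vs_ltr_halved"] = ltr_pair_age(
                    row[l5], row[l3], rate,
                    cpg_reference=(consensus[l5], consensus[l3]),
                )
            except ValueError:
                skipped.append(("ltr_vs_ltr_halved", "no comparable sites"))
        else:
            skipped.append(("ltr_vs_ltr_halved", "one or both LTRs absent"))
        if not components:
            report = AgeReport(locus_name=name, reliable=False)
            report.excluded = skipped
            reports[name] = report
            continue
        report = aggregate_age(components, sd_threshold, locus_name=name)
        report.excluded = skipped + report.excluded
        reports[name] = report
    return reports


# ---------------------------------------------------------------------------
# comparative genomics
# ---------------------------------------------------------------------------


@dataclass
class OcaResult:
    species: str
    window: tuple[float, float]  # (divergence of OCA, next older speciation)
    lineage_specific_losses: list[str] = field(default_factory=list)


def infer_oca(
    presence_row: Mapping[str, bool], species_panel: Mapping[str, float]
) -> OcaResult:
    """Oldest common ancestor of an integration from presence/absence data.

    The OCA is the present species with the largest divergence time; the age
    window runs from that divergence to the next older speciation (infinity
    when the OCA is the oldest species in the panel).  A locus present only
    in human gets OCA "human" with window (0, youngest split).  Species
    younger than the OCA but scored absent are lineage-specific losses.
    """
    ordered = sorted(species_panel, key=lambda s: (species_panel[s], s))
    present = [s for s in ordered if presence_row.get(s, False)]
    if not present:
        hi = species_panel[ordered[0]] if ordered else math.inf
        return OcaResult(species="human", window=(0.0, hi))
    oca = present[-1]
    idx = ordered.index(oca)
    hi = species_panel[ordered[idx + 1]] if idx + 1 < len(ordered) else math.inf
    losses = [
        s for s in ordered[:idx] if not presence_row.get(s, False)
    ]
    return OcaResult(species=oca, window=(species_panel[oca], hi), lineage_specific_losses=losses)


def consistency_check(report: AgeReport, slack: float = 0.25) -> str:
    """Flag whether the clock age agrees with the comparative OCA window.

    Consistent iff mean age >= lower window bound * (1 - slack).  Loci with
    a withheld (unreliable) age are flagged "not_evaluated".
    """
    if report.mean_age is None or report.oca_window is None:
        report.consistent = "not_evaluated"
        return report.consistent
    lower = report.oca_window[0]
    report.consistent = (
        "consistent" if report.mean_age >= lower * (1.0 - slack) else "inconsistent"
    )
    return report.consistent


def write_age_table(reports: Mapping[str, AgeReport], path) -> None:
    """Age report TSV: locus, age (or '-'), relative SD, OCA, consistency."""
    with open(path, "w") as fh:
        fh.write("locus\tmean_age_My\trelative_sd\toca\toca_window\tconsistent\tn_components\n")
        for name in sorted(reports):
            r = reports[name]
            age = f"{r.mean_age:.1f}" if r.mean_age is not None else "-"
            rsd = f"{r.relative_sd:.3f}" if r.relative_sd is not None else "-"
            window = (
                f"{r.oca_window[0]:g}-{r.oca_window[1]:g}" if r.oca_window else "-"
            )
            fh.write(
                f"{name}\t{age}\t{rsd}\t{r.oca_species or '-'}\t{window}"
                f"\t{r.consistent or '-'}\t{len(r.components)}\n"
            )
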