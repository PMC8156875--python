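"""Packaged HML7 locus tables and panel defaults.

The proviral locus table (23 loci with coordinates, ages and oldest common
ancestors), the gene-colocalization table (11 loci) and the per-chromosome
element counts ship as versioned TSVs so the headline group statistics can
be recomputed without network access.  The per-chromosome solitary-LTR
distribution is a synthetic stand-in (see the file header) except for the
chromosomes whose counts are published.  Files are checksum-gated against
accidental edits.
"""

from __future__ import annotations

import hashlib
from importlib import resources
from pathlib import Path

import pandas as pd

_CHECKSUMS = {
    "grch38_lengths.tsv": "6a978e2808feadfde9e9782644d653661ede3f9c8c9091ae6808f8e89310fb74",
    "solo_ltr_counts_synthetic.tsv": "3014df056f8dd29e2dcbd3a0c07c03cb05252d6f5a70ba165d903685339a2854",
    "species_panel.tsv": "2cc3516908441717aa58281063bb0847bf35407d4a69ac782139b7510252ec52",
    "table1_loci.tsv": "4c67637921004e8435713c4903081e553fee695e437932997282ca0136edf3e2",
    "table2_gene_context.tsv": "ffbe89960af2105179c0a39c7ee78a492b46650e070d3afc718ac770d59f54df",
}


class FixtureChecksumError(RuntimeError):
    pass


def _fixture_path(name: str) -> Path:
    path = resources.files("ervscribe.data") / name
    data = path.read_bytes()
    digest = hashlib.sha256(data).hexdigest()
    if digest != _CHECKSUMS[name]:
        raise FixtureChecksumError(
            f"fixture {name} checksum mismatch: {digest} != {_CHECKSUMS[name]}"
        )
    return Path(str(path))


def _read(name: str) -> pd.DataFrame:
    return pd.read_csv(_fixture_path(name), sep="\t", comment="#", dtype=str)


def load_locus_table() -> pd.DataFrame:
    """The 23 proviral loci: coordinates (1-based inclusive), age, OCA, flags."""
    df = _read("table1_loci.tsv")
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    df["age_My"] = pd.to_numeric(df["age_My"], errors="coerce")
    df["oca_note"] = df["oca_note"].fillna("")
    return df

def load_gene_context_table() -> pd.DataFrame:
    """The 11 gene-colocalized proviral loci with orientation calls."""
    return _read("table2_gene_context.tsv")


def load_chromosome_counts() -> pd.DataFrame:
    """Per-chromosome provirus and solitary-LTR counts (solo part synthetic)."""
    df = _read("solo_ltr_counts_synthetic.tsv")
    df["proviruses"] = df["proviruses"].astype(int)
    df["solo_ltrs"] = df["solo_ltrs"].astype(int)
    return df


def load_grch38_lengths() -> dict[str, int]:
    df = _read("grch38_lengths.tsv")
    return dict(zip(df["chrom"], df["length"].astype(int)))


def load_species_panel() -> dict[str, float]:
    df = _read("species_panel.tsv")
    return dict(zip(df["species"], df["divergence_My"].astype(float)))


def count_oca_first_integrations(locus_table: pd.DataFrame | None = None) -> dict[str, int]:
    """First-integration counts per oldest common ancestor species."""
    if locus_table is None:
        locus_table = load_locus_table()
    counts: dict[str, int] = {}
    for oca in locus_table["oca"]:
        counts[oca] = counts.get(oca, 0) + 1
    return counts


def summary_from_fixtures() -> dict:
    """Headline group statistics recomputed from the packaged tables."""
    loci = load_locus_table()
    genic = load_gene_context_table()
    counts = load_chromosome_counts()
    n_prov = len(loci)
    n_solo = int(counts["solo_ltrs"].sum())
    n_genic = len(genic)
    n_centro = int((loci["region_flag"] != "other").sum())
    n_complete = int(loci["structure"].isin(["complete", "near_complete"]).sum())
    n_sense = int((genic["orientation"] == "sense").sum())
    return {
        "n_proviruses": n_prov,
        "n_solo_ltrs": n_solo,
        "n_total": n_prov + n_solo,
        "solo_to_provirus_ratio": f"1:{round(n_solo / n_prov)}" if n_prov and n_solo else "-",
        "genic_fraction_percent": round(100.0 * n_genic / n_prov),
        "centromeric_or_pericentromeric_percent": round(100.0 * n_centro / n_prov),
        "complete_percent": round(100.0 * n_complete / n_prov),
        "n_sense_oriented": n_sense,
        "observed_per_chromosome": dict(
            zip(counts["chrom"], (counts["proviruses"] + counts["solo_ltrs"]).astype(int))
        ),
        "oca_first_integrations": count_oca_first_integrations(loci),
    }
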