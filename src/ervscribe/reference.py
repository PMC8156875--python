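"""Annotated proviral reference model.

The HML7 group reference is a ~9.5-kb provirus with the canonical
5'LTR--gag--pro--pol--env--3'LTR layout.  The two LTRs are the same length
(they are identical at the moment of integration) and *gag*/*pro* overlap by
43 nt, reflecting the betaretroviral translation strategy in which *pro* is
reached from *gag* by readthrough or ribosomal frameshifting.

Coordinates are stored 1-based inclusive, as in the feature tables this model
mirrors; helper methods convert to Python slices where needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: 1-based inclusive feature intervals of the HML7 group reference provirus.
HML7_FEATURES: dict[str, tuple[int, int]] = {
    "LTR5": (1, 897),
    "gag": (1056, 2924),
    "pro": (2882, 3929),
    "pol": (4010, 6487),
    "env": (6701, 8647),
    "LTR3": (8650, 9546),
}

#: Total length of the HML7 reference provirus (bp).
HML7_REFERENCE_LENGTH = 9546

#: Feature order along the provirus.
FEATURE_ORDER = ("LTR5", "gag", "pro", "pol", "env", "LTR3")


@dataclass(frozen=True)
class ReferenceModel:
    """A proviral reference sequence with named feature intervals.

    Parameters
    ----------
    sequence
        Uppercase nucleotide sequence of the full provirus.
    features
        Map of feature name to 1-based inclusive ``(start, end)``.  Must
        contain ``LTR5`` and ``LTR3`` of equal length; gene features may
        overlap (*gag*/*pro* do in the HML7 layout).
    name
        Label used when the reference participates in alignments.
    """

    sequence: str
    features: Mapping[str, tuple[int, int]] = field(
        default_factory=lambda: dict(HML7_FEATURES)
    )
    name: str = "HML7_reference"

    def __post_init__(self) -> None:
        n = len(self.sequence)
        if n == 0:
            raise ValueError("reference sequence is empty")
        for feat, (s, e) in self.features.items():
            if not (1 <= s <= e <= n):
                raise ValueError(
                    f"feature {feat} interval ({s}, {e}) outside sequence of length {n}"
                )
        if "LTR5" not in self.features or "LTR3" not in self.features:
            raise ValueError("reference model requires both LTR5 and LTR3 features")
        if self.ltr_length("LTR5") != self.ltr_length("LTR3"):
            raise ValueError("LTR5 and LTR3 must have equal length")

    # -- accessors ---------------------------------------------------------

    def __len__(self) -> int:
        return len(self.sequence)

    def feature_interval(self, name: str) -> tuple[int, int]:
        """1-based inclusive interval of a feature."""
        return tuple(self.features[name])

    def feature_slice(self, name: str) -> slice:
        s, e = self.features[name]
        return slice(s - 1, e)

    def feature_sequence(self, name: str) -> str:
        return self.sequence[self.feature_slice(name)]

    def ltr_length(self, which: str = "LTR5") -> int:
        s, e = self.features[which]
        return e - s + 1

    @property
    def internal_span(self) -> tuple[int, int]:
        """1-based inclusive span of the internal (gag..env) portion."""
        genes = [f for f in self.features if f not in ("LTR5", "LTR3")]
        if not genes:
            raise ValueError("reference model has no internal features")
        return (
            min(self.features[g][0] for g in genes),
            max(self.features[g][1] for g in genes),
        )

    # -- I/O ---------------------------------------------------------------

    def to_files(self, fasta_path: str | Path, features_path: str | Path) -> None:
        """Write the reference as FASTA plus a feature TSV (1-based inclusive)."""
        SeqIO.write(
            [SeqRecord(Seq(self.sequence), id=self.name, description="")],
            str(fasta_path),
            "fasta",
        )
        with open(features_path, "w") as fh:
            fh.write("feature\tstart\tend\n")
            for feat, (s, e) in self.features.items():
                fh.write(f"{feat}\t{s}\t{e}\n")

    @classmethod
    def from_files(
        cls, fasta_path: str | Path, features_path: str | Path
    ) -> "ReferenceModel":
        rec = next(SeqIO.parse(str(fasta_path), "fasta"))
        features: dict[str, tuple[int, int]] = {}
        with open(features_path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            idx = {c: i for i, c in enumerate(header)}
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 3:
                    continue
                features[parts[idx["feature"]]] = (
                    int(parts[idx["start"]]),
                    int(parts[idx["end"]]),
                )
        return cls(sequence=str(rec.seq).upper(), features=features, name=rec.id)
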