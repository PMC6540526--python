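"""Core domain types: clones, repertoires, germline references, clinical records.

A *clone* is a unique assembled variable-region nucleotide sequence within one
(sample, chain); its ``count`` is the number of supporting reads. A
*repertoire* is the set of clones for one sample and one immunoglobulin /
T-cell-receptor locus, together with the sample's total RNA-seq library size
(the denominator used to normalize clone abundance).
"""

from __future__ import annotations

from dataclasses import dataclass, field

CHAINS = ("IGHG", "IGHA", "IGHM", "IGHD", "IGK", "IGL", "TRA", "TRB")

_SEQ_ALPHABET = frozenset("ACGTN")


@dataclass(frozen=True)
class CloneRecord:
    """One unique assembled BCR/TCR sequence and its read support."""

    sample_id: str
    chain: str
    sequence: str
    count: int
    v_call: str | None = None

    def __post_init__(self) -> None:
        if self.chain not in CHAINS:
            raise ValueError(f"unknown chain {self.chain!r}; expected one of {CHAINS}")
        if not self.sequence:
            raise ValueError("clone sequence must be non-empty")
        bad = set(self.sequence.upper()) - _SEQ_ALPHABET
        if bad:
            raise ValueError(f"sequence contains non-ACGTN characters: {sorted(bad)}")
        if self.count < 0:
            raise ValueError("clone count must be non-negative")

    @property
    def has_ambiguous_bases(self) -> bool:
        """True if the sequence contains N; such clones are counted but
        excluded from germline-identity alignment."""
        return "N" in self.sequence.upper()


@dataclass
class Repertoire:
    """All clones of one chain in one sample, plus the library size."""

    sample_id: str
    chain: str
    clones: list[CloneRecord] = field(default_factory=list)
    library_size: int = 1

    def __post_init__(self) -> None:
        if self.library_size <= 0:
            raise ValueError("library_size must be positive")
        seqs = [c.sequence for c in self.clones]
        if len(seqs) != len(set(seqs)):
            raise ValueError("clone sequences must be unique within a repertoire")

    @property
    def counts(self) -> list[int]:
        return [c.count for c in self.clones]

    @property
    def total_count(self) -> int:
        return sum(c.count for c in self.clones)

    @property
    def richness(self) -> int:
        """Species richness: number of clones with positive count."""
        return sum(1 for c in self.clones if c.count > 0)


@dataclass
class GermlineReference:
    """Germline V-gene nucleotide sequences keyed by gene name (IMGT-style)."""

    entries: dict[str, str]

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("germline reference must contain at least one entry")
        for name, seq in self.entries.items():
            if not seq:
                raise ValueError(f"germline entry {name!r} has an empty sequence")


@dataclass
class ClinicalRecord:
    """Per-patient survival outcome and covariates.

    ``os_time`` is overall-survival time in days; ``os_event`` is 1 for death,
    0 for censoring. ``response`` labels immunotherapy outcome where known.
    """

    sample_id: str
    os_time: float
    os_event: int
    age: float | None = None
    sex: str | None = None
    stage: str | None = None
    tissue_site: str | None = None
    response: str | None = None
    subtype: str | None = None

    def __post_init__(self) -> None:
        if self.os_time < 0:
            raise ValueError("os_time must be non-negative")
        if self.os_event not in (0, 1):
            raise ValueError("os_event must be 0 or 1")
        if self.response is not None and self.response not in ("responder", "non_responder"):
            raise ValueError(f"unknown response label {self.response!r}")
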