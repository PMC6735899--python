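"""Packaged fixture data.

All packaged data are synthetic, constructed for testing and worked
examples: a 300-codon toy ORF with amplicon flanks and four nested
domain annotations, and a 23-record validated-mutant phenotype table
whose fold-change values are synthetic (built so that exactly one record
is discordant with its screen expectation, the outcome the concordance
bookkeeping is designed to surface).
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from .landscape import PhenotypeRecord, read_phenotypes
from .reference import DomainAnnotation, OrfReference, read_reference


def _data_path(name: str) -> Path:
    return Path(resources.files("poolscreen").joinpath("data", name))  # type: ignore[arg-type]


def load_toy_reference() -> tuple[OrfReference, list[DomainAnnotation]]:
    """The packaged 300-codon synthetic ORF and its 4 nested domains."""
    return read_reference(_data_path("toy_orf.fasta"), _data_path("toy_domains.tsv"))


def load_validated_mutants() -> list[PhenotypeRecord]:
    """Synthetic 23-record validated-mutant phenotype table (one discordant)."""
    return read_phenotypes(_data_path("validated_mutants_synthetic.tsv"))
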