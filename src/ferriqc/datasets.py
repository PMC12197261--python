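"""Packaged reference dataset: ferric-iron ecotoxicity records.

The shipped table holds 47 literature acute/chronic endpoint records for
Fe3+ and freshwater organisms (31 acute over 18 species / 17 genera; 16
chronic over 4 species / 4 genera), the input for criteria derivation.
"""

from __future__ import annotations

from importlib import resources

from .toxdata import ToxicityRecord, read_toxicity_csv


def ferric_iron_toxicity_path():
    return resources.files("ferriqc.data") / "ferric_iron_toxicity.csv"


def load_ferric_iron_toxicity() -> list[ToxicityRecord]:
    with resources.as_file(ferric_iron_toxicity_path()) as p:
        return read_toxicity_csv(p)
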