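"""Packaged example data."""

from __future__ import annotations

from importlib.resources import as_file, files
from pathlib import Path

from .ddi_kb import KnowledgeBase, load_kb

__all__ = ["example_kb", "example_kb_path"]


def example_kb_path() -> Path:
    """Path to the packaged example knowledge base.

    A synthetic reconstruction of twelve well-documented interaction pairs
    around oral anticoagulants and antiplatelets (warfarin with proton-pump
    inhibitors, aspirin, clopidogrel, allopurinol, ...), with preferred-term
    style effect-term sets. Severities and effect descriptions are
    illustrative, not compendium extracts.
    """
    with as_file(files("ddiscreen").joinpath("data/example_kb.tsv")) as p:
        return Path(p)


def example_kb() -> KnowledgeBase:
    """Load the packaged example knowledge base."""
    return load_kb(example_kb_path(), version_label="ddiscreen-example-kb")
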