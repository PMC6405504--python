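"""Sexual size dimorphism and Rensch's rule in stingless bees.

Comparative analysis of caste body sizes on time-calibrated phylogenies:
SSD index computation, Felsenstein's independent contrasts, major-axis
allometric regression with an isometry test, ML ancestral reconstruction of
continuous traits, and simulators for validating every stage.
"""

__version__ = "0.1.0"

from importlib import resources


def bundled_table_path():
    """Path to the bundled 44-species intertegular-width table."""
    return resources.files("stingless_ssd.data") / "meliponini_intertegular_widths.csv"


def load_bundled_table():
    """Bundled caste size table as a species-indexed DataFrame."""
    from .phylo_io import read_trait_table

    with resources.as_file(bundled_table_path()) as p:
        return read_trait_table(p)
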