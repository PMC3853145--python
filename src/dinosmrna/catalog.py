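"""Reference catalog of 21 validated Symbiodinium microadriaticum smRNAs.

The catalog ships with the package (``data/smrna_catalog.tsv``): 8
miRNAs (mismatched guide/star duplexes) and 13 siRNAs (perfectly
complementary duplexes) identified independently across 9 experimental
treatments of cultured S. microadriaticum, with precursor stem-loop
lengths, minimum free energies, and mature/star read counts. The
``star_conditions`` column is the number of treatments in which the
star (passenger) strand was detected.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

_CATALOG_RESOURCE = "smrna_catalog.tsv"


def load_reference_catalog() -> pd.DataFrame:
    """Load the shipped 21-smRNA catalog as a DataFrame."""
    ref = resources.files("dinosmrna") / "data" / _CATALOG_RESOURCE
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t")
    return df
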