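"""Desikan-Killiany 84-node parcellation labels and display coordinates.

Nodes follow the common cortical + subcortical scheme used for structural
connectomes: 34 cortical regions per hemisphere, 7 subcortical grey-matter
structures per hemisphere, plus one cerebellar node per hemisphere
(42 per hemisphere, 84 total). Left-hemisphere nodes come first.

The bundled centroid table (``data/dk84_centroids_synthetic.tsv``) holds
SYNTHETIC schematic coordinates laid out on a hemispheric grid; it exists
only so exported ``.node`` files have a valid coordinate column and must
not be interpreted as anatomical MNI positions.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

#: FreeSurfer cortical region names, alphabetical order.
DK_CORTICAL = (
    "bankssts",
    "caudalanteriorcingulate",
    "caudalmiddlefrontal",
    "cuneus",
    "entorhinal",
    "frontalpole",
    "fusiform",
    "inferiorparietal",
    "inferiortemporal",
    "insula",
    "isthmuscingulate",
    "lateraloccipital",
    "lateralorbitofrontal",
    "lingual",
    "medialorbitofrontal",
    "middletemporal",
    "paracentral",
    "parahippocampal",
    "parsopercularis",
    "parsorbitalis",
    "parstriangularis",
    "pericalcarine",
    "postcentral",
    "posteriorcingulate",
    "precentral",
    "precuneus",
    "rostralanteriorcingulate",
    "rostralmiddlefrontal",
    "superiorfrontal",
    "superiorparietal",
    "superiortemporal",
    "supramarginal",
    "temporalpole",
    "transversetemporal",
)

#: Subcortical structures plus cerebellum, one node each per hemisphere.
DK_SUBCORTICAL = (
    "thalamus",
    "caudate",
    "putamen",
    "pallidum",
    "accumbens",
    "hippocampus",
    "amygdala",
    "cerebellum",
)


def dk84_labels() -> list[str]:
    """Return the canonical 84 node labels, left hemisphere first."""
    labels = []
    for hemi in ("lh", "rh"):
        labels.extend(f"ctx-{hemi}-{name}" for name in DK_CORTICAL)
        labels.extend(f"{hemi}-{name}" for name in DK_SUBCORTICAL)
    return labels


def dk84_centroids() -> pd.DataFrame:
    """Load the synthetic schematic centroid table (label, x, y, z)."""
    ref = resources.files("faconn") / "data" / "dk84_centroids_synthetic.tsv"
    with resources.as_file(ref) as path:
        table = pd.read_csv(path, sep="\t")
    return table
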