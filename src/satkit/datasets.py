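"""Bundled reference data.

The insect-order time tree carries TimeTree-of-life node ages (MY) for the
six orders in which yellow-mealworm satDNA families have been detected:
Coleoptera, Lepidoptera, Diptera, Hymenoptera, Hemiptera, Blattodea. The ages
that drive minimal-age estimates are the Coleoptera splits from Blattodea
(380 MY), Hemiptera (360 MY) and Hymenoptera (340 MY). The Tenebrionidae
emergence age (165 MY) bounds families detected only in Tenebrio molitor.
"""

from __future__ import annotations

from importlib import resources

from satkit.trees import DatedTree, dated_tree_from_string

TENEBRIONIDAE_EMERGENCE_MY = 165.0

FOCAL_ORDER = "Coleoptera"


def insect_orders_timetree() -> DatedTree:
    """The dated insect-order tree (ultrametric Newick, branch lengths in MY)."""
    text = (
        resources.files("satkit").joinpath("data/insect_orders_timetree.nwk").read_text()
    )
    return dated_tree_from_string(text, dialect="branch_lengths")
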