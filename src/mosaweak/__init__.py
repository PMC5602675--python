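"""mosaweak: multi-strategy phylogenetics on discrete morphological
matrices — parsimony search under equal/implied weights, clade supports,
fossilized birth–death tip dating, and weak-spot evaluation of
phylogenetic clade definitions."""

from importlib import resources

__version__ = "0.1.0"


def packaged_data(name: str):
    """Path to a packaged data file (table1.json, ordered_chars.txt, ...)."""
    return resources.files("mosaweak.data").joinpath(name)
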