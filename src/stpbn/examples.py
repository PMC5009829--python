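"""Bundled example networks, loadable offline.

``p53_network`` is the four-gene major switch of the p53 pathway
(ATM, p53, Wip1, Mdm2); ``two_node_L1`` the simplest reachable 2-node
network; ``three_node_control_template`` a lower-triangle 3-node template
whose third node carries a control input.
"""

from __future__ import annotations

from importlib import resources

from .network import BooleanNetwork, parse_network

__all__ = ["example_path", "example_text", "p53_network", "two_node_L1",
           "three_node_control_template"]

_FILES = {
    "p53": "p53.bn",
    "two_node_L1": "two_node_L1.bn",
    "three_node_control": "three_node_control.bn",
}


def example_text(name: str) -> str:
    """Raw network-file text of a bundled example."""
    try:
        filename = _FILES[name]
    except KeyError:
        raise KeyError(f"unknown example {name!r}; choose from {sorted(_FILES)}") from None
    return (resources.files("stpbn") / "data" / filename).read_text()


def example_path(name: str):
    """Filesystem path of a bundled example file."""
    return resources.files("stpbn") / "data" / _FILES[name]


def p53_network() -> BooleanNetwork:
    return parse_network(example_text("p53"), name="p53")


def two_node_L1() -> BooleanNetwork:
    return parse_network(example_text("two_node_L1"), name="two_node_L1")


def three_node_control_template() -> BooleanNetwork:
    return parse_network(example_text("three_node_control"), name="three_node_control")
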