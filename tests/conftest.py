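"""Shared fixtures: small hand-built ontologies and expression fixtures."""

from __future__ import annotations

import numpy as np
import pytest

from scretrieve.ontology import OntologyDAG, OntoTerm


@pytest.fixture
def immune_dag() -> OntologyDAG:
    """cell -> {lymphocyte -> {T cell, B cell}, myeloid cell}."""
    terms = [
        OntoTerm("CL:0000000", "cell"),
        OntoTerm("CL:0000542", "lymphocyte"),
        OntoTerm("CL:0000084", "T cell", synonyms=("T lymphocyte",)),
        OntoTerm("CL:0000236", "B cell", synonyms=("B lymphocyte",)),
        OntoTerm("CL:0000763", "myeloid cell"),
    ]
    edges = [
        ("CL:0000542", "CL:0000000"),
        ("CL:0000084", "CL:0000542"),
        ("CL:0000236", "CL:0000542"),
        ("CL:0000763", "CL:0000000"),
    ]
    return OntologyDAG(terms, edges, {"CL"})


@pytest.fixture
def chain_dag() -> OntologyDAG:
    """A 4-term chain: leaf -> mid -> upper -> root."""
    terms = [
        OntoTerm("CL:0000003", "leaf cell"),
        OntoTerm("CL:0000002", "mid cell"),
        OntoTerm("CL:0000001", "upper cell"),
        OntoTerm("CL:0000000", "root cell"),
    ]
    edges = [
        ("CL:0000003", "CL:0000002"),
        ("CL:0000002", "CL:0000001"),
        ("CL:0000001", "CL:0000000"),
    ]
    return OntologyDAG(terms, edges, {"CL"})


def reachable(dag: OntologyDAG, src: str, dst: str) -> bool:
    """Brute-force reachability along child->parent edges (test oracle)."""
    seen, stack = set(), [src]
    while stack:
        node = stack.pop()
        if node == dst and node != src:
            return True
        for parent in dag.parents(node):
            if parent not in seen:
                seen.add(parent)
                stack.append(parent)
    return dst in seen


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
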