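"""Shared fixtures: small parsed documents, random document/table generators
used as independent oracles for round-trip and risk tests."""

from __future__ import annotations

import json
import random

import pytest

import wisedeid as w

MINIMAL_PATIENT = {
    "resourceType": "Patient",
    "id": "pat-1",
    "name": [{"family": "Doe", "given": ["Jane", "Q"]}],
    "birthDate": "1984-07-21",
    "gender": "female",
    "address": [{"city": "Tallinn", "postalCode": "10115"}],
}


@pytest.fixture(scope="session")
def registry():
    return w.default_registry()


@pytest.fixture(scope="session")
def policy():
    return w.default_policy()


@pytest.fixture
def patient_doc():
    return w.parse(json.dumps(MINIMAL_PATIENT), source_id="pat-1")


def random_json_doc(seed: int, max_depth: int = 8, max_fanout: int = 5) -> dict:
    """A random FHIR-shaped JSON document (no nested arrays, as in FHIR)."""
    rng = random.Random(seed)

    def scalar():
        return rng.choice([
            rng.randint(-1000, 1000),
            round(rng.uniform(-10, 10), 3),
            rng.choice([True, False]),
            "".join(rng.choices("abcdefgh xyz", k=rng.randint(1, 12))),
        ])

    def node(depth, in_list=False):
        if depth >= max_depth or rng.random() < 0.35:
            return scalar()
        if not in_list and rng.random() < 0.3:
            return [node(depth + 1, in_list=True)
                    for _ in range(rng.randint(1, max_fanout))]
        return {f"k{rng.randint(0, 30)}_{i}": node(depth + 1)
                for i in range(rng.randint(1, max_fanout))}

    doc = {f"field{i}": node(1) for i in range(rng.randint(1, max_fanout))}
    doc["resourceType"] = rng.choice(["Patient", "Observation", "Basic"])
    return doc


def count_leaves(obj) -> int:
    """Independent recursive leaf enumeration (oracle for flatten)."""
    if isinstance(obj, dict):
        return sum(count_leaves(v) for v in obj.values())
    if isinstance(obj, list):
        return sum(count_leaves(v) for v in obj)
    return 1


def random_quasi_table(seed: int, n_max: int = 1000, n_cols_max: int = 5):
    """Random categorical table of quasi-identifier values (oracle input)."""
    rng = random.Random(seed)
    n = rng.randint(2, n_max)
    n_cols = rng.randint(1, n_cols_max)
    cardinalities = [rng.randint(1, 12) for _ in range(n_cols)]
    return [tuple(f"v{rng.randint(0, c - 1)}" for c in cardinalities)
            for _ in range(n)]
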