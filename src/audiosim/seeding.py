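"""Deterministic seed derivation.

A single master seed drives every random draw in a run. Each component
(material generation, cohort sampling, each session, each scorer) receives
its own child seed derived from the master seed and a component name, so
adding a component never perturbs another component's stream.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["child_seed", "child_rng"]


def child_seed(master_seed: int, name: str) -> int:
    """Derive a stable 31-bit child seed from ``master_seed`` and a name."""
    digest = hashlib.sha256(f"{int(master_seed)}:{name}".encode()).digest()
    return int.from_bytes(digest[:4], "little") & 0x7FFFFFFF


def child_rng(master_seed: int, name: str) -> np.random.Generator:
    """A fresh :class:`numpy.random.Generator` for one named component."""
    return np.random.default_rng(child_seed(master_seed, name))
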