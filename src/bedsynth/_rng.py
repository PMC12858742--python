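"""Seed fan-out.

A single user-facing integer seed is expanded into independent per-subsystem
streams by keying a :class:`numpy.random.SeedSequence` with CRC-32 digests of
string labels.  Adding a new subsystem (a new label) therefore never perturbs
the draws of existing ones, and identical (seed, labels) pairs always yield
identical streams.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["child_rng", "child_seed"]


def child_seed(seed: int, *labels: str | int) -> np.random.SeedSequence:
    """Derive a SeedSequence for subsystem ``labels`` from a global ``seed``."""
    key = tuple(
        zlib.crc32(lab.encode("utf-8")) if isinstance(lab, str) else int(lab)
        for lab in labels
    )
    return np.random.SeedSequence(int(seed), spawn_key=key)


def child_rng(seed: int, *labels: str | int) -> np.random.Generator:
    """A generator on the stream keyed by ``labels`` under global ``seed``."""
    return np.random.default_rng(child_seed(seed, *labels))
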