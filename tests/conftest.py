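"""Shared fixtures and helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from rtcrispr.profiles import load_profiles, load_repeat_db, profile_dict
from rtcrispr.synth import ArraySpec, random_dna, realize_array

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def profiles():
    return load_profiles()


@pytest.fixture(scope="session")
def profile_map():
    return profile_dict()


@pytest.fixture(scope="session")
def repeat_db():
    return load_repeat_db()


def planted_array_contig(
    spec: ArraySpec,
    seed: int,
    left_pad: int = 300,
    right_pad: int = 300,
    trim_leader: int = 0,
) -> tuple[str, int, int]:
    """A contig carrying one planted array; returns (contig, start, end).

    ``trim_leader`` removes that many bases from the leader-side end of the
    array block (left for forward arrays, right for reverse ones), which is
    how tests manufacture short-flank (band NA) situations.
    """
    rng = np.random.default_rng(seed)
    pre = random_dna(rng, left_pad)
    block, a0, a1 = realize_array(spec, rng)
    if trim_leader:
        if spec.orientation == "forward":
            block = block[trim_leader:]
            a0 -= trim_leader
            a1 -= trim_leader
        else:
            block = block[: len(block) - trim_leader]
    post = random_dna(rng, right_pad)
    contig = pre + block + post
    return contig, left_pad + a0 + 1, left_pad + a1 + 1


def matching_array(arrays, start: int, end: int, slack_bp: int = 70):
    """The detected array matching a planted (start, end) within one repeat
    unit of slack at each boundary, or None."""
    for a in arrays:
        if abs(a.start - start) <= slack_bp and abs(a.end - end) <= slack_bp:
            return a
    return None
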