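"""Shared builders and strategies for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from txweave.models import TranscriptModel

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_transcript(
    tid="T1",
    chrom="chr1",
    strand="+",
    exons=((0, 100),),
    cds=(),
    **kwargs,
) -> TranscriptModel:
    return TranscriptModel(
        id=tid,
        chrom=chrom,
        strand=strand,
        exons=[tuple(e) for e in exons],
        cds_segments=[tuple(c) for c in cds],
        **kwargs,
    )


def random_transcript(rng: np.random.Generator, tid="T", chrom="chr1") -> TranscriptModel:
    """A random valid transcript: sorted non-overlapping exons."""
    n_exons = int(rng.integers(1, 6))
    pos = int(rng.integers(0, 200))
    exons = []
    for _ in range(n_exons):
        length = int(rng.integers(20, 200))
        exons.append((pos, pos + length))
        pos += length + int(rng.integers(30, 300))
    strand = "+" if rng.random() < 0.5 else "-"
    return make_transcript(tid=tid, strand=strand, exons=exons)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
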