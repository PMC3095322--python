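"""Shared fixtures and independent oracles for the test suite."""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pytest

from mirtarmap import pipeline, simulate

# ---------------------------------------------------------------------------
# independent scoring oracle (no imports from mirtarmap.scoring)
# ---------------------------------------------------------------------------

_WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_WOB = {("G", "U"), ("U", "G")}


def oracle_window_min(columns, positions, window=20):
    """Brute-force window-minimum penalty: enumerates every 20-position
    window and re-sums the penalties from scratch with its own pair table."""
    covered = sorted(p for p in positions if p is not None)
    assert len(covered) >= window
    best = None
    for w in range(covered[0], covered[-1] - window + 2):
        idxs = [k for k, p in enumerate(positions)
                if p is not None and w <= p <= w + window - 1]
        total = 0.0
        for k in idxs:
            mb, tb = columns[k]
            if tb == "-":
                total += 2.0
            elif (mb, tb) in _WC:
                total += 0.0
            elif (mb, tb) in _WOB:
                total += 0.5
            else:
                total += 1.5 if 2 <= positions[k] <= 7 else 1.0
        for k in range(idxs[0], idxs[-1] + 1):
            if positions[k] is None:
                total += 2.0
        if best is None or total < best:
            best = total
    return best


def random_duplex(rng: np.random.Generator):
    """A random gapped duplex (columns + miRNA positions) for property
    tests: random pair classes per position, occasional bulges on either
    side."""
    bases = "ACGU"
    comp = {"A": "U", "U": "A", "G": "C", "C": "G"}
    wob = {"G": "U", "U": "G"}
    m = int(rng.integers(20, 27))
    columns = []
    positions = []
    for pos in range(1, m + 1):
        qb = bases[rng.integers(4)]
        roll = rng.random()
        if roll < 0.55:
            tb = comp[qb]
        elif roll < 0.70 and qb in wob:
            tb = wob[qb]
        elif roll < 0.85:
            choices = [b for b in bases if b != comp[qb]]
            tb = choices[rng.integers(len(choices))]
        else:
            tb = "-"  # miRNA base bulged out (target gap)
        columns.append((qb, tb))
        positions.append(pos)
        if pos < m and rng.random() < 0.08:
            columns.append(("-", bases[rng.integers(4)]))
            positions.append(None)
    return tuple(columns), tuple(positions)


# ---------------------------------------------------------------------------
# session-scoped end-to-end artefacts
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def bundle(tmp_path_factory) -> simulate.FixtureBundle:
    """The seed-1 synthetic bundle."""
    out = tmp_path_factory.mktemp("bundle")
    return simulate.generate(out, seed=1)


@pytest.fixture(scope="session")
def pipeline_run(bundle, tmp_path_factory):
    """One full pipeline run over the seed-1 bundle; returns
    (report, out_dir, manifest)."""
    out = tmp_path_factory.mktemp("pipeline_out")
    cfg = pipeline.RunConfig.from_bundle_dir(bundle.out_dir, out)
    report = pipeline.run_pipeline(cfg)
    return report, out, bundle.manifest


@pytest.fixture(scope="session")
def store_path(pipeline_run) -> Path:
    _, out, _ = pipeline_run
    return out / "sites.sqlite"
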