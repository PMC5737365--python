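"""Shared fixtures: simulated study bundles at several scales.

The heavy fixtures are session-scoped so the expensive simulate->validate
loops run once and are shared by the acceptance and property tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from svrecur.model import SVValidator
from svrecur.simulate import SimConfig, simulate_bundle
from svrecur.sv_model import SVType

MINI_TYPES = [
    SVType.DEL, SVType.INS, SVType.INV, SVType.DUP_TANDEM,
    SVType.DUP_INV, SVType.DEL_INV, SVType.DEL_DUP,
]


def _labelled_table(bundle, results):
    t = results.table.copy()
    n_true = len(bundle.truth)
    t["is_true"] = [True] * n_true + [False] * (len(t) - n_true)
    t["zyg"] = [e.zygosity for e in bundle.truth] + ["-"] * (len(t) - n_true)
    return t


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240)


@pytest.fixture(scope="session")
def mini_study(tmp_path_factory):
    """Small full loop: 400 kb genome, 2 SVs per type, x20, with false set."""
    cfg = SimConfig(
        genome_len=400_000,
        n_svs={t: 2 for t in MINI_TYPES},
        depth=20,
        seed=3,
        min_gap=4_000,
        edge_margin=15_000,
    )
    out = tmp_path_factory.mktemp("mini")
    bundle = simulate_bundle(cfg, str(out))
    svs = bundle.truth.svs() + bundle.false_svs
    model = SVValidator(bundle.fasta, bundle.bam, svs)
    results = model.fit()
    return {
        "bundle": bundle,
        "model": model,
        "results": results,
        "table": _labelled_table(bundle, results),
    }


@pytest.fixture(scope="session")
def clean_study(tmp_path_factory):
    """Error-free reads (accuracy 1.0) at x40: limit-case behaviour."""
    cfg = SimConfig(
        genome_len=400_000,
        n_svs={t: 2 for t in MINI_TYPES},
        depth=40,
        accuracy_mean=1.0,
        seed=5,
        min_gap=4_000,
        edge_margin=15_000,
    )
    out = tmp_path_factory.mktemp("clean")
    bundle = simulate_bundle(cfg, str(out), with_false=False)
    model = SVValidator(bundle.fasta, bundle.bam, bundle.truth.svs())
    results = model.fit()
    return {
        "bundle": bundle,
        "model": model,
        "results": results,
        "table": _labelled_table(bundle, results),
    }


@pytest.fixture(scope="session")
def full_study(tmp_path_factory):
    """The headline study: 5 Mb diploid genome, 350 mixed SVs, x20 coverage,
    plus the equal-size relocated false call set."""
    import time

    cfg = SimConfig(seed=11)
    out = tmp_path_factory.mktemp("full")
    t0 = time.time()
    bundle = simulate_bundle(cfg, str(out))
    svs = bundle.truth.svs() + bundle.false_svs
    model = SVValidator(bundle.fasta, bundle.bam, svs)
    results = model.fit()
    elapsed = time.time() - t0
    return {
        "bundle": bundle,
        "model": model,
        "results": results,
        "table": _labelled_table(bundle, results),
        "elapsed": elapsed,
        "config": cfg,
    }
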