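"""Shared fixtures: small PWM sets, grammars and feature tables."""

from __future__ import annotations

import numpy as np
import pytest

import promgram as pg


@pytest.fixture(scope="session")
def toy_pwms():
    """Eight sharp PWMs of widths 6-9 (anchor first)."""
    return pg.generate_toy_pwms(8, (6, 9), seed=11, dominant=0.9,
                                threshold=0.82)


@pytest.fixture(scope="session")
def strong_grammar(toy_pwms):
    """A conserved 6-motif chain with tight spacing near the right end."""
    ids = [p.motif_id for p in toy_pwms]
    return pg.GrammarSpec(ids[:6], [0.95] * 6, [{18: 0.85, 30: 0.15}] * 5,
                          anchor_offset=30)


@pytest.fixture(scope="session")
def training_table(toy_pwms, strong_grammar):
    """Feature table from 40+40 strong-grammar training sequences."""
    records, _ = pg.generate_training_set(strong_grammar, toy_pwms,
                                          40, 40, seed=101)
    return pg.build_feature_table(records, toy_pwms)


@pytest.fixture(scope="session")
def fitted_model(training_table):
    return pg.fit(pg.build_structure(8), training_table)


def make_vector(M, S, L, seq_id="v", label="unknown"):
    return pg.FeatureVector(seq_id, label, list(M), list(S), list(L))
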