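"""Shared fixtures: the hand-checkable toy cohort and the default synthetic
benchmark (generated once per session)."""

from __future__ import annotations

from datetime import date
from types import SimpleNamespace

import numpy as np
import pytest

import workuprec as w


def item(cid: str, domain: str = "condition", qualifier: str = "none") -> w.ClinicalItem:
    return w.ClinicalItem(cid, domain, qualifier)


def episode(pid, query, targets, referral=date(2018, 3, 1), visit=date(2018, 4, 1)):
    return w.ReferralEpisode(
        patient_id=pid,
        referral_date=referral,
        specialty_visit_date=visit,
        query_items=frozenset(query),
        target_items=frozenset(targets),
    )


X = item("X")
Y = item("Y")
L1 = item("L1", "measurement")
L2 = item("L2", "measurement")


@pytest.fixture
def toy_episodes():
    """Five-patient cohort with counts small enough to verify by hand:
    N_X=3, N_Y=3, N_{X,L1}=3, N_{X,L2}=1, N_{Y,L1}=1, N_{Y,L2}=1."""
    return [
        episode("P1", {X}, {L1, L2}),
        episode("P2", {X, Y}, {L1}),
        episode("P3", {Y}, {L2}),
        episode("P4", {X}, {L1}),
        episode("P5", {Y}, set()),
    ]


@pytest.fixture
def toy_matrix(toy_episodes):
    return w.build_matrix(toy_episodes)


def random_episodes(rng: np.random.Generator, max_patients=50, max_items=20):
    """A random small cohort for oracle-equivalence checks."""
    n_pat = int(rng.integers(1, max_patients + 1))
    n_items = int(rng.integers(2, max_items + 1))
    n_q = max(1, n_items // 2)
    q_items = [item(f"q{i}") for i in range(n_q)]
    t_items = [item(f"t{i}", "measurement") for i in range(n_items - n_q)]
    eps = []
    for p in range(n_pat):
        q = {it for it in q_items if rng.random() < 0.4}
        t = {it for it in t_items if rng.random() < 0.3}
        if not q:
            q = {q_items[int(rng.integers(0, n_q))]}
        eps.append(episode(f"P{p}", q, t))
    return eps


@pytest.fixture(scope="session")
def benchmark():
    """Default desk-scale benchmark: 2000 train + 500 test patients, default
    planted structure, fixed seed; trained matrix and matched background."""
    cfg = w.default_config()
    events, referrals, visits, truth = w.generate_cohort(cfg, seed=1)
    events = w.categorize_events(events)
    events, vocab = w.filter_rare_items(events, min_support=10)
    episodes = w.build_episodes(events, referrals, visits)
    train, test = w.split_by_year(episodes, test_year=2020)
    matrix = w.build_matrix(train)
    background = w.generate_background(
        cfg, seed=2, query_counts=matrix.query_counts, n_cohort=matrix.n_cohort
    )
    return SimpleNamespace(
        config=cfg, events=events, vocab=vocab, truth=truth,
        train=train, test=test, matrix=matrix, background=background,
    )
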