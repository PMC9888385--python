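"""Divergence score, opposite-pattern filter, and ranking."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from angiolnc import (
    SimulationConfig,
    divergence_score,
    filter_opposite_pattern,
    gen_contrast_tables,
    rank_candidates,
    run_screen,
)
from angiolnc.screen import GROUP_DOWN, GROUP_UP, CandidateRecord

from conftest import contrast_frame


@pytest.mark.parametrize(
    "fc_hx, fc_hg, fc_tnf, expected",
    [
        (2.0, -1.0, -1.5, 6.5),
        (-2.0, 1.0, 1.5, 6.5),  # symmetric under joint negation
        (0.7, 0.7, 0.7, 0.0),
        (-3.2, -3.2, -3.2, 0.0),
        (1.0, 1.0, -1.0, 2.0),
    ],
)
def test_divergence_score_values(fc_hx, fc_hg, fc_tnf, expected):
    assert divergence_score(fc_hx, fc_hg, fc_tnf) == pytest.approx(expected)


@pytest.mark.parametrize("bad", [float("nan"), float("inf"), float("-inf")])
def test_divergence_score_rejects_nonfinite(bad):
    with pytest.raises(ValueError):
        divergence_score(bad, 0.0, 0.0)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    fcs=st.tuples(*[st.floats(-10, 10) for _ in range(3)]),
    c=st.floats(0.01, 100),
)
def test_divergence_score_scale_equivariant(fcs, c):
    base = divergence_score(*fcs)
    scaled = divergence_score(*(c * f for f in fcs))
    assert scaled == pytest.approx(c * base, rel=1e-9, abs=1e-9)


def _three_tables(hx_fc, hx_p, hg_fc, hg_p, tnf_fc, tnf_p):
    return (
        contrast_frame(["g1"], [hx_fc], [hx_p]),
        contrast_frame(["g1"], [hg_fc], [hg_p]),
        contrast_frame(["g1"], [tnf_fc], [tnf_p]),
    )


@pytest.mark.parametrize(
    "args, included, group",
    [
        # hx up, both diabetic significantly down
        ((1.5, 0.01, -1.0, 0.01, -0.8, 0.04), True, GROUP_UP),
        # all three positive and significant: same-sign exclusion
        ((1.5, 0.01, 1.0, 0.01, 0.8, 0.04), False, None),
        # no significant diabetic contrast
        ((1.5, 0.01, -1.0, 0.2, -0.8, 0.2), False, None),
        # one significant opposite diabetic contrast suffices ("and/or")
        ((1.5, 0.01, -1.0, 0.01, 0.8, 0.4), True, GROUP_UP),
        # a significant same-sign diabetic contrast vetoes
        ((1.5, 0.01, -1.0, 0.01, 0.8, 0.01), False, None),
        # hx not significant
        ((1.5, 0.2, -1.0, 0.01, -0.8, 0.01), False, None),
        # hx down, diabetic up: mirror group
        ((-1.5, 0.01, 1.0, 0.01, 0.8, 0.04), True, GROUP_DOWN),
    ],
)
def test_filter_opposite_pattern_cases(args, included, group):
    records = filter_opposite_pattern(*_three_tables(*args), alpha=0.05)
    if included:
        assert [r.gene_id for r in records] == ["g1"]
        assert records[0].group == group
    else:
        assert records == []


def test_filter_requires_shared_genes_and_valid_alpha():
    hx = contrast_frame(["a"], [1.0], [0.01])
    hg = contrast_frame(["b"], [1.0], [0.01])
    with pytest.raises(ValueError, match="share no genes"):
        filter_opposite_pattern(hx, hg, hg, alpha=0.05)
    with pytest.raises(ValueError, match="alpha"):
        filter_opposite_pattern(hx, hx, hx, alpha=1.5)


def test_filter_rejects_missing_padj():
    bad = contrast_frame(["a"], [1.0], [0.01]).drop(columns=["padj"])
    good = contrast_frame(["a"], [-1.0], [0.01])
    with pytest.raises(ValueError, match="padj"):
        filter_opposite_pattern(bad, good, good, alpha=0.05)


def test_rank_ties_broken_lexicographically():
    genes = ["B", "C", "A"]
    hx = contrast_frame(genes, [1.0, 2.0, 2.0], [0.01] * 3)
    hg = contrast_frame(genes, [-0.5, -1.0, -1.0], [0.01] * 3)
    tnf = contrast_frame(genes, [-0.5, -1.25, -1.25], [0.01] * 3)
    records = [CandidateRecord(g, GROUP_UP) for g in genes]
    ranked = rank_candidates(records, hx, hg, tnf)
    # A and C tie at 6.25; A wins lexicographically; B scores 3.0
    assert [(r.gene_id, r.rank) for r in ranked] == [("A", 1), ("C", 2), ("B", 3)]
    assert ranked[0].score == pytest.approx(6.25)


def test_rank_empty_input():
    t = contrast_frame(["a"], [1.0], [0.01])
    assert rank_candidates([], t, t, t) == []


def test_rank_drops_genes_missing_from_a_table():
    hx = contrast_frame(["a", "b"], [1.0, 2.0], [0.01, 0.01])
    partial = contrast_frame(["a"], [-1.0], [0.01])
    records = [CandidateRecord("a", GROUP_UP), CandidateRecord("b", GROUP_UP)]
    ranked = rank_candidates(records, hx, partial, partial)
    assert [r.gene_id for r in ranked] == ["a"]


def _oracle_screen(hx, hg, tnf, alpha):
    """Loop-based reimplementation used as an independent oracle."""
    tabs = {}
    for name, t in (("hx", hx), ("hg", hg), ("tnf", tnf)):
        tabs[name] = {
            row.gene_id: (row.log2fc, row.padj) for row in t.itertuples()
        }
    shared = set(tabs["hx"]) & set(tabs["hg"]) & set(tabs["tnf"])
    picked = []
    for g in shared:
        fc_hx, p_hx = tabs["hx"][g]
        if p_hx >= alpha or fc_hx == 0:
            continue
        n_opp, veto = 0, False
        for d in ("hg", "tnf"):
            fc, p = tabs[d][g]
            if p < alpha:
                if fc * fc_hx < 0:
                    n_opp += 1
                else:
                    veto = True
        if veto or n_opp == 0:
            continue
        score = abs(fc_hx - tabs["hg"][g][0]) + abs(fc_hx - tabs["tnf"][g][0])
        picked.append((g, score))
    picked.sort(key=lambda t: (-t[1], t[0]))
    return [(g, s, i + 1) for i, (g, s) in enumerate(picked)]


def test_screen_matches_bruteforce_oracle():
    rng = np.random.default_rng(1234)
    for _ in range(5):
        n = int(rng.integers(20, 100))
        genes = [f"g{i}" for i in range(n)]
        tables = [
            contrast_frame(
                genes,
                rng.normal(0, 2, n).round(3),
                rng.random(n).round(3),
            )
            for _ in range(3)
        ]
        got = run_screen(*tables, alpha=0.2)
        expected = _oracle_screen(*tables, alpha=0.2)
        assert list(zip(got.gene_id, got.score.round(9), got["rank"])) == [
            (g, round(s, 9), r) for g, s, r in expected
        ]


def test_screen_invariant_to_row_order():
    (hx, hg, tnf), _ = gen_contrast_tables(SimulationConfig(n_genes=100, n_planted=5, seed=2))
    ref = run_screen(hx, hg, tnf)
    shuffled = run_screen(
        hx.sample(frac=1, random_state=0),
        hg.sample(frac=1, random_state=1),
        tnf.sample(frac=1, random_state=2),
    )
    pd.testing.assert_frame_equal(ref.reset_index(drop=True), shuffled.reset_index(drop=True))


def test_screen_recovers_planted_candidates_one_run():
    cfg = SimulationConfig(n_genes=1000, n_planted=10, effect_size=2.0, noise_sd=0.25, seed=11)
    (hx, hg, tnf), truth = gen_contrast_tables(cfg)
    result = run_screen(hx, hg, tnf, alpha=0.05)
    assert set(result.head(10).gene_id) == set(truth.planted_candidate_ids)
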