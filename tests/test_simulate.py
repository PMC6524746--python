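"""Generator conformance: design constraints, the switch rule, NB noise."""

import numpy as np
import pytest

from eqdtu import simulate as sim
from eqdtu.simulate import SimConfig


def test_infeasible_config_rejected():
    with pytest.raises(ValueError, match="infeasible|isoform"):
        SimConfig(isoforms_per_gene=(5, 5), exons_per_gene=(2, 2), exon_length=(100, 100))


def test_single_gene_single_isoform_layout():
    config = SimConfig(
        n_genes=1, isoforms_per_gene=(1, 1), exons_per_gene=(2, 2),
        exon_length=(150, 150), seed=0,
    )
    ann, seqs = sim.simulate_transcriptome(config)
    # one isoform: shared exon 0 + private exon 1 -> both exons, length 300
    assert len(ann) == 1
    assert len(seqs[ann.records[0].transcript_id]) == 300


def test_same_seed_identical_transcriptome():
    config = SimConfig(n_genes=10, seed=3)
    a1, s1 = sim.simulate_transcriptome(config)
    a2, s2 = sim.simulate_transcriptome(config)
    assert s1 == s2
    assert [(r.transcript_id, r.exons) for r in a1] == [
        (r.transcript_id, r.exons) for r in a2
    ]


def test_config_conformance_over_many_genes():
    config = SimConfig(n_genes=50, seed=9)
    ann, seqs = sim.simulate_transcriptome(config)
    genes = ann.genes()
    assert len(genes) == 50
    lo, hi = config.isoforms_per_gene
    for gene_id, recs in genes.items():
        assert lo <= len(recs) <= hi
        # all isoforms share the gene's first exon
        shared = set.intersection(*(set(r.exons) for r in recs))
        assert shared
        # isoform exon subsets are pairwise distinct
        assert len({r.exons for r in recs}) == len(recs)
    for tx, seq in seqs.items():
        rec = ann.transcript(tx)
        assert len(seq) == rec.length


def test_abundances_normalised_per_gene():
    config = SimConfig(n_genes=20, seed=4)
    ann, _ = sim.simulate_transcriptome(config)
    _, props = sim.assign_abundances(config, ann)
    for gene_id, recs in ann.genes().items():
        total = sum(props[r.transcript_id] for r in recs)
        assert total == pytest.approx(1.0, abs=1e-12)
        if len(recs) == 1:
            assert props[recs[0].transcript_id] == pytest.approx(1.0)


def test_gene_expression_mean_matches_lognormal(rng):
    config = SimConfig(n_genes=100, seed=1, gene_expr_sigma=1.0)
    ann, _ = sim.simulate_transcriptome(config)
    draws = []
    for rep in range(100):
        expr, _ = sim.assign_abundances(config, ann, np.random.default_rng(rep))
        draws.extend(expr.values())
    draws = np.asarray(draws)  # 10k draws
    expected_mean = np.exp(0.5)  # lognormal(0, 1)
    se = draws.std(ddof=1) / np.sqrt(len(draws))
    assert abs(draws.mean() - expected_mean) < 3 * se


# ---------------------------------------------------------------------------
# the DTU switch
# ---------------------------------------------------------------------------


def _switch_fixture():
    from eqdtu.formats_io import TranscriptAnnotation, TranscriptRecord

    ann = TranscriptAnnotation(
        records=[
            TranscriptRecord("g1.t1", "g1", "c", "+", ((0, 100),)),
            TranscriptRecord("g1.t2", "g1", "c", "+", ((0, 150),)),
            TranscriptRecord("g1.t3", "g1", "c", "+", ((0, 200),)),
            TranscriptRecord("g2.t1", "g2", "c", "+", ((300, 400),)),
            TranscriptRecord("g2.t2", "g2", "c", "+", ((300, 500),)),
        ]
    )
    return ann


def test_switch_exchanges_top_two():
    ann = _switch_fixture()
    props = {"g1.t1": 0.6, "g1.t2": 0.3, "g1.t3": 0.1, "g2.t1": 0.7, "g2.t2": 0.3}
    out = sim.apply_dtu_switch(props, {"g1"}, ann)
    assert out["g1.t1"] == 0.3 and out["g1.t2"] == 0.6 and out["g1.t3"] == 0.1
    assert out["g2.t1"] == 0.7 and out["g2.t2"] == 0.3  # non-DTU untouched


def test_switch_of_equal_proportions_is_identity():
    ann = _switch_fixture()
    props = {"g1.t1": 0.45, "g1.t2": 0.45, "g1.t3": 0.1, "g2.t1": 0.5, "g2.t2": 0.5}
    out = sim.apply_dtu_switch(props, {"g1", "g2"}, ann)
    assert out == props


def test_switch_conserves_gene_totals_random(rng):
    config = SimConfig(n_genes=30, seed=6)
    ann, _ = sim.simulate_transcriptome(config)
    _, props = sim.assign_abundances(config, ann)
    dtu = sim.select_dtu_genes(config, ann)
    out = sim.apply_dtu_switch(props, dtu, ann)
    for gene_id, recs in ann.genes().items():
        before = sum(props[r.transcript_id] for r in recs)
        after = sum(out[r.transcript_id] for r in recs)
        assert after == pytest.approx(before, abs=1e-12)
        if gene_id not in dtu:
            for r in recs:
                assert out[r.transcript_id] == props[r.transcript_id]


def test_switch_preserves_expected_gene_expression(tiny_design, tiny_config):
    """DTU without differential gene expression: per-gene totals equal across conditions."""
    annotation, _, truth = tiny_design
    c1, c2 = tiny_config.conditions
    for gene_id, recs in annotation.genes().items():
        t1 = sum(truth.expected_counts[c1][r.transcript_id] for r in recs)
        t2 = sum(truth.expected_counts[c2][r.transcript_id] for r in recs)
        assert t2 == pytest.approx(t1, rel=1e-9)


def test_single_isoform_gene_in_dtu_set_errors():
    ann = _switch_fixture()
    from eqdtu.formats_io import TranscriptAnnotation, TranscriptRecord

    ann = TranscriptAnnotation(
        records=ann.records + [TranscriptRecord("g3.t1", "g3", "c", "+", ((600, 700),))]
    )
    with pytest.raises(ValueError, match="<2 isoforms"):
        sim.apply_dtu_switch({"g3.t1": 1.0}, {"g3"}, ann)


# ---------------------------------------------------------------------------
# reads and EC counts
# ---------------------------------------------------------------------------


def test_reads_deterministic_under_seed(tiny_design, tiny_config):
    annotation, sequences, truth = tiny_design
    r1 = sim.simulate_reads(annotation, sequences, truth, tiny_config, np.random.default_rng(5))
    r2 = sim.simulate_reads(annotation, sequences, truth, tiny_config, np.random.default_rng(5))
    for s in r1:
        assert [(a.read_id, a.sequence, a.true_source) for a in r1[s]] == [
            (a.read_id, a.sequence, a.true_source) for a in r2[s]
        ]


def test_read_counts_match_expectations(tiny_config):
    """Per-transcript mean counts over replicates within 3 SE of depth x abundance."""
    config = SimConfig(
        n_genes=8, depth=20_000, seed=7, k=15, n_replicates=20, nb_dispersion=0.05
    )
    annotation, sequences, truth = sim.simulate_experiment_design(config)
    rng = np.random.default_rng(0)
    counts = sim._transcript_counts_for_samples(config, annotation, truth, rng)
    c1 = config.conditions[0]
    reps = [s for s in counts if s.startswith(c1)]
    for rec in annotation:
        t = rec.transcript_id
        mu = truth.expected_counts[c1][t]
        if mu < 50:
            continue
        obs = np.array([counts[s][t] for s in reps], dtype=float)
        var = mu + config.nb_dispersion * mu**2
        se = np.sqrt(var / len(reps))
        assert abs(obs.mean() - mu) < 3 * se + 1e-9


def test_poisson_limit_variance_over_mean(tiny_config):
    config = SimConfig(n_genes=5, depth=50_000, seed=2, k=15, n_replicates=30, nb_dispersion=0.0)
    annotation, sequences, truth = sim.simulate_experiment_design(config)
    counts = sim._transcript_counts_for_samples(
        config, annotation, truth, np.random.default_rng(1)
    )
    c1 = config.conditions[0]
    reps = [s for s in counts if s.startswith(c1)]
    ratios = []
    for rec in annotation:
        t = rec.transcript_id
        obs = np.array([counts[s][t] for s in reps], dtype=float)
        if obs.mean() > 100:
            ratios.append(obs.var(ddof=1) / obs.mean())
    assert 0.5 < np.median(ratios) < 2.0


def test_truth_ledger_complete_and_sources_valid(tiny_design, tiny_config):
    annotation, sequences, truth = tiny_design
    reads = sim.simulate_reads(
        annotation, sequences, truth, tiny_config, np.random.default_rng(8)
    )
    ids = [r.read_id for recs in reads.values() for r in recs]
    assert len(ids) == len(set(ids))  # every read exactly once
    for recs in reads.values():
        for r in recs[:200]:
            t, p = r.true_source
            assert r.sequence == sequences[t][p : p + tiny_config.read_length]


def test_fast_path_trivial_ec_structure():
    config = SimConfig(
        n_genes=1, isoforms_per_gene=(1, 1), exons_per_gene=(2, 2),
        exon_length=(200, 200), depth=500, seed=3, k=15,
    )
    annotation, sequences, truth = sim.simulate_experiment_design(config)
    matrix = sim.simulate_ec_counts(annotation, sequences, truth, config)
    # single transcript: all mass in the singleton EC
    assert len(matrix.rows) == 1
    assert matrix.rows[0].transcripts == (annotation.records[0].transcript_id,)


def test_fast_path_identical_sequences_share_ec():
    from eqdtu.formats_io import TranscriptAnnotation, TranscriptRecord

    seq = "".join(np.random.default_rng(0).choice(list("ACGT"), size=300))
    ann = TranscriptAnnotation(
        records=[
            TranscriptRecord("g1.t1", "g1", "c", "+", ((0, 300),)),
            TranscriptRecord("g1.t2", "g1", "c", "+", ((0, 300),)),
        ]
    )
    config = SimConfig(n_genes=1, depth=1000, seed=1, k=15)
    truth = sim.SimTruth(
        dtu_genes=set(),
        proportions={"S1": {"g1.t1": 0.5, "g1.t2": 0.5}, "S2": {"g1.t1": 0.5, "g1.t2": 0.5}},
        expected_counts={
            "S1": {"g1.t1": 500.0, "g1.t2": 500.0},
            "S2": {"g1.t1": 500.0, "g1.t2": 500.0},
        },
    )
    matrix = sim.simulate_ec_counts(ann, {"g1.t1": seq, "g1.t2": seq}, truth, config)
    assert [r.transcripts for r in matrix.rows] == [("g1.t1", "g1.t2")]


def test_fast_path_agrees_with_read_path(tiny_config):
    """EC count proportions: analytic profile path vs pseudo-aligned reads."""
    from eqdtu.ec_core import build_ec_matrix
    from eqdtu.pseudoalign import build_index, pseudoalign_sample

    config = SimConfig(n_genes=5, depth=50_000, seed=13, k=15, n_replicates=1)
    annotation, sequences, truth = sim.simulate_experiment_design(config)
    index = build_index(sequences, k=config.k)

    reads = sim.simulate_reads(
        annotation, sequences, truth, config, np.random.default_rng(21)
    )
    sample = f"{config.conditions[0]}_rep1"
    table = pseudoalign_sample(reads[sample], index, sample_id=sample)
    read_counts = dict(table.named_entries())

    truth2 = sim.SimTruth(
        dtu_genes=truth.dtu_genes,
        proportions=truth.proportions,
        expected_counts=truth.expected_counts,
        transcript_counts={sample: truth.transcript_counts[sample]},
    )
    matrix = sim.simulate_ec_counts(
        annotation, sequences, truth2, config, rng=np.random.default_rng(22), index=index
    )
    fast_counts = {
        frozenset(ec.transcripts): int(c)
        for ec, c in zip(matrix.rows, matrix.counts[:, 0])
    }
    total_r = sum(read_counts.values())
    total_f = sum(fast_counts.values())
    for ec in set(read_counts) | set(fast_counts):
        pr = read_counts.get(ec, 0) / total_r
        pf = fast_counts.get(ec, 0) / total_f
        n = max(read_counts.get(ec, 0), fast_counts.get(ec, 0))
        se = np.sqrt(max(pr * (1 - pr), 1e-9) / max(total_r, 1))
        assert abs(pr - pf) <= 3 * se + 5.0 / total_r


def test_null_feature_matrix_shape_and_labels():
    df, st = sim.simulate_null_feature_matrix(n_genes=10, seed=0)
    assert st.conditions == ["S1", "S2"]
    assert df["gene_id"].nunique() == 10
    assert (df.drop(columns="gene_id").to_numpy() >= 0).all()
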