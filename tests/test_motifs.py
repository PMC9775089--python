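import numpy as np
import pytest

from grnpipe import motifs as M
from grnpipe.synthetic import simulate_promoters

CONSENSUS = "TGTGGTCA"  # non-palindromic


def planted_model(strength=0.95, consensus=CONSENSUS):
    return M.MotifModel("planted", M.pwm_from_consensus(consensus, strength))


# ----------------------------------------------------------------- basics


def test_encode_and_revcomp():
    assert list(M.encode("ACGTN")) == [0, 1, 2, 3, 4]
    assert M.reverse_complement("ACGTN") == "NACGT"


def test_pwm_from_consensus():
    pwm = M.pwm_from_consensus("ACGT", 0.9)
    assert np.allclose(pwm.sum(axis=0), 1.0)
    assert "".join("ACGT"[i] for i in pwm.argmax(axis=0)) == "ACGT"


def test_motif_model_validates_columns():
    bad = np.full((4, 6), 0.3)
    with pytest.raises(ValueError, match="sum to 1"):
        M.MotifModel("bad", bad)


def test_information_content_extremes():
    sharp = M.MotifModel("s", M.pwm_from_consensus("AAAA", 1.0))
    flat = M.MotifModel("f", np.full((4, 4), 0.25))
    assert np.allclose(sharp.information_content(), 2.0)
    assert np.allclose(flat.information_content(), 0.0)


# ------------------------------------------------------------- extraction


@pytest.fixture()
def genome(tmp_path):
    rng = np.random.default_rng(0)
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 5000)])
    path = tmp_path / "genome.fa"
    path.write_text(">chr1\n" + "\n".join(seq[i : i + 80] for i in range(0, 5000, 80)) + "\n")
    return path, seq


def _bed(tmp_path, lines):
    path = tmp_path / "genes.bed"
    path.write_text("\n".join(lines) + "\n")
    return path


def test_extract_upstream_plus_strand(tmp_path, genome):
    path, seq = genome
    bed = _bed(tmp_path, ["chr1\t2000\t3000\tgeneA\t0\t+"])
    records = M.extract_upstream(path, bed, flank=1000)
    assert records == [("geneA", seq[1000:2000].upper())]


def test_extract_upstream_minus_strand(tmp_path, genome):
    path, seq = genome
    bed = _bed(tmp_path, ["chr1\t2000\t3000\tgeneB\t0\t-"])
    records = M.extract_upstream(path, bed, flank=1000)
    assert records == [("geneB", M.reverse_complement(seq[3000:4000].upper()))]


def test_extract_upstream_truncation_warns(tmp_path, genome):
    path, seq = genome
    bed = _bed(tmp_path, ["chr1\t400\t900\tgeneC\t0\t+"])
    with pytest.warns(UserWarning, match="truncated"):
        records = M.extract_upstream(path, bed, flank=1000)
    assert records == [("geneC", seq[0:400].upper())]


def test_extract_upstream_missing_chromosome(tmp_path, genome):
    path, _ = genome
    bed = _bed(tmp_path, ["chr9\t2000\t3000\tgeneD\t0\t+"])
    with pytest.raises(KeyError, match="chr9"):
        M.extract_upstream(path, bed, flank=1000)


# --------------------------------------------------------------- scanning


def test_score_sites_finds_planted_word():
    rng = np.random.default_rng(1)
    flank = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 60)])
    seq = flank[:17] + CONSENSUS + flank[17:52]
    site = M.score_sites(planted_model(), seq)
    assert (site.offset, site.strand) == (17, "+")


def test_score_sites_uniform_pwm_tie_rule():
    uniform = M.MotifModel("u", np.full((4, 6), 0.25))
    site = M.score_sites(uniform, "ACGTACGTACGT")
    assert (site.offset, site.strand, site.score) == (0, "+", 0.0)


def test_score_sites_revcomp_symmetry():
    rng = np.random.default_rng(2)
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 80)])
    fwd = M.score_sites(planted_model(), seq)
    rev = M.score_sites(planted_model(), M.reverse_complement(seq))
    assert fwd.score == pytest.approx(rev.score)


def test_score_sites_rejects_short_sequence():
    with pytest.raises(ValueError, match="shorter"):
        M.score_sites(planted_model(), "ACGT")


# -------------------------------------------------------------- discovery


@pytest.fixture(scope="module")
def planted_sequences():
    records, truth = simulate_promoters(
        planted_model(), 30, 120, plant_fraction=1.0, gc=0.5, seed=7
    )
    return records, truth


def test_discover_recovers_planted_consensus(planted_sequences):
    records, truth = planted_sequences
    models = M.discover_motifs(
        records, wmin=6, wmax=10, n_motifs=1, seed=1, n_starts=2, n_null=0
    )
    m = models[0]
    assert 6 <= m.width <= 20
    assert np.allclose(m.pwm.sum(axis=0), 1.0)
    assert CONSENSUS in m.consensus or m.consensus in CONSENSUS or (
        M.reverse_complement(CONSENSUS) in m.consensus
    )
    # discovered width may be 8 +/- a column, shifting site starts by one
    site_map = {t[0]: t[1] for t in truth}
    hits = sum(1 for s in m.sites if abs(site_map[s.seq_id] - s.offset) <= 1)
    assert hits / len(truth) >= 0.8


def test_discover_objective_monotone(planted_sequences):
    records, _ = planted_sequences
    models = M.discover_motifs(
        records, wmin=8, wmax=8, n_motifs=2, seed=3, n_starts=2, n_null=0
    )
    for m in models:
        hist = np.array(m.objective_history)
        assert np.all(np.diff(hist) >= -1e-8 * (1 + np.abs(hist[:-1])))


def test_discover_null_flagged_non_significant():
    rng = np.random.default_rng(5)
    records = [
        (f"R{i}", "".join(np.array(list("ACGT"))[rng.integers(0, 4, 100)]))
        for i in range(20)
    ]
    models = M.discover_motifs(
        records, wmin=8, wmax=8, n_motifs=1, seed=5, n_starts=2, n_null=10
    )
    assert models[0].significant is False


def test_discover_skips_short_sequences(planted_sequences):
    records, _ = planted_sequences
    with pytest.warns(UserWarning, match="skipped"):
        models = M.discover_motifs(
            records + [("tiny", "ACG")], wmin=6, wmax=6, n_motifs=1, seed=0,
            n_starts=1, n_null=0,
        )
    assert models[0].width == 6


def test_discover_requires_two_sequences():
    with pytest.raises(ValueError, match="at least 2"):
        M.discover_motifs([("a", "ACGTACGTACGT")], wmin=6, wmax=6)


def test_site_recovery_monotone_in_information_content():
    recalls = []
    for strength in (0.55, 0.75, 0.95):
        model = planted_model(strength)
        records, truth = simulate_promoters(model, 25, 100, 1.0, 0.5, seed=11)
        found = M.discover_motifs(
            records, wmin=8, wmax=8, n_motifs=1, seed=2, n_starts=2, n_null=0
        )[0]
        site_map = {t[0]: t[1] for t in truth}
        hits = sum(1 for s in found.sites if site_map.get(s.seq_id) == s.offset)
        recalls.append(hits / len(truth))
    assert recalls[0] <= recalls[1] <= recalls[2]


# ------------------------------------------------------------- comparison


def test_compare_identity():
    q = planted_model()
    match = M.compare_motifs(q, [q], n_null=200, seed=0)[0]
    assert match.offset == 0
    assert match.orientation == "forward"
    assert match.similarity == pytest.approx(1.0)
    assert match.p <= 0.05


def test_compare_own_reverse_complement():
    # non-palindromic motif: forward alignment cannot tie at 1.0
    q = planted_model(consensus="AAACGTGC")
    match = M.compare_motifs(q, [q.reverse_complemented()], n_null=100, seed=0)[0]
    assert match.orientation == "reverse-complement"
    assert match.similarity == pytest.approx(1.0)


def test_compare_symmetric_under_joint_revcomp():
    q = planted_model()
    d = M.MotifModel("d", M.pwm_from_consensus("AACCGGTTAA", 0.8))
    m1 = M.compare_motifs(q, [d], n_null=50, seed=1)[0]
    m2 = M.compare_motifs(q.reverse_complemented(), [d.reverse_complemented()],
                          n_null=50, seed=1)[0]
    assert m1.similarity == pytest.approx(m2.similarity)


def _random_high_ic_pwm(rng, width=8):
    """Sharp PWM whose columns are all distinct (unlike a flat consensus)."""
    raw = rng.dirichlet([0.3] * 4, size=width).T
    sharp = raw**3
    return sharp / sharp.sum(axis=0, keepdims=True)


def test_compare_true_motif_beats_shuffled_decoys():
    wins = 0
    for seed in range(10):
        rng = np.random.default_rng(seed)
        truth_pwm = _random_high_ic_pwm(rng)
        db = [M.MotifModel("true", truth_pwm)]
        for d in range(10):
            db.append(M.MotifModel(f"dec{d}", truth_pwm[:, rng.permutation(8)]))
        noisy = 0.8 * truth_pwm + 0.2 * np.full((4, 8), 0.25)
        query = M.MotifModel("q", noisy / noisy.sum(axis=0, keepdims=True))
        best = M.compare_motifs(query, db, n_null=200, seed=seed)[0]
        wins += int(best.target == "true")
    assert wins >= 9


def test_compare_empty_database_rejected():
    with pytest.raises(ValueError, match="empty"):
        M.compare_motifs(planted_model(), [])


# ---------------------------------------------------------------------- IO


def test_meme_roundtrip(tmp_path):
    m = planted_model()
    path = tmp_path / "motifs.meme"
    M.write_meme([m], path)
    loaded = M.read_meme(path)
    assert len(loaded) == 1
    assert loaded[0].width == m.width
    assert np.allclose(loaded[0].pwm, m.pwm, atol=1e-5)


def test_jaspar_roundtrip(tmp_path):
    m = planted_model()
    path = tmp_path / "db.pfm"
    M.write_jaspar_pfm([m], path)
    loaded = M.read_jaspar_pfm(path)
    assert len(loaded) == 1
    assert loaded[0].width == m.width
    assert np.allclose(loaded[0].pwm, m.pwm, atol=0.02)


def test_fasta_roundtrip(tmp_path):
    records = [("s1", "ACGTACGT"), ("s2", "TTTTACGT")]
    path = tmp_path / "seqs.fa"
    M.write_fasta(records, path)
    assert M.read_fasta(path) == records
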