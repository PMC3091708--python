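"""Frame cascade: homology tiers, codon model, coding scan, translation."""
import dataclasses
import math

import numpy as np
import pandas as pd
import pytest

from ventannot.errors import ConfigError, InputError, TrainingError
from ventannot.frames import (CODONS, CascadeParams, FrameCall, STOP_CODONS,
                              _best_window, assign_frames_homology,
                              calibrate_null_threshold, reverse_complement,
                              run_cascade, scan_coding, train_codon_model,
                              translate)
from ventannot.io import HIT_COLUMNS
from ventannot.synthetic import SimulationConfig, simulate_contigs

from conftest import truth_calls


def _hit_row(qseqid, evalue, bitscore=100.0, frame=1, sseqid="s1"):
    return dict(qseqid=qseqid, sseqid=sseqid, pident=80.0, length=100,
                mismatch=20, gapopen=0, qstart=1, qend=300, sstart=1,
                send=100, evalue=evalue, bitscore=bitscore, sframe=frame,
                staxid=4)


def _hits(rows):
    return pd.DataFrame(rows, columns=HIT_COLUMNS)


class TestTranslate:
    @pytest.mark.parametrize("seq, frame, expected", [
        ("ATGGCC", 1, "MA"),
        ("GGCCAT", -1, "MA"),            # reverse-complement symmetry
        ("ATGNAA", 1, "MX"),             # ambiguous codon -> X
        ("TATGGCC", 2, "MA"),
        ("ATGTAAGCC", 1, "M*A"),         # stop rendered '*'
    ])
    def test_examples(self, seq, frame, expected):
        assert translate(seq, frame) == expected

    @pytest.mark.parametrize("frame", [0, 4, -4])
    def test_invalid_frame(self, frame):
        with pytest.raises(InputError):
            translate("ATGGCC", frame)


class TestHomologyTiers:
    def test_strict_cutoff_assigns(self):
        hits = _hits([_hit_row("q1", 1e-7, frame=2)])
        calls, unassigned = assign_frames_homology(hits, 1e-6, "strict")
        assert calls["q1"].frame == 2 and calls["q1"].tier == "strict"
        assert not unassigned

    def test_relaxed_cutoff_rescues(self):
        hits = _hits([_hit_row("q1", 1e-5, frame=-3)])
        calls, unassigned = assign_frames_homology(hits, 1e-6, "strict")
        assert not calls and unassigned == {"q1"}
        calls2, _ = assign_frames_homology(hits, 1e-2, "relaxed")
        assert calls2["q1"].frame == -3 and calls2["q1"].tier == "relaxed"

    def test_best_evalue_wins(self):
        hits = _hits([_hit_row("q1", 1e-9, frame=2),
                      _hit_row("q1", 1e-8, frame=-1)])
        calls, _ = assign_frames_homology(hits, 1e-6, "strict")
        assert calls["q1"].frame == 2

    def test_evalue_tie_broken_by_bitscore(self):
        hits = _hits([_hit_row("q1", 1e-9, bitscore=90.0, frame=1),
                      _hit_row("q1", 1e-9, bitscore=150.0, frame=3)])
        calls, _ = assign_frames_homology(hits, 1e-6, "strict")
        assert calls["q1"].frame == 3

    def test_unsorted_evalues_rejected(self):
        hits = _hits([_hit_row("q1", 1e-5), _hit_row("q1", 1e-9)])
        with pytest.raises(InputError, match="q1"):
            assign_frames_homology(hits, 1e-6, "strict")

    def test_lower_cutoff_never_assigns_more(self):
        rng = np.random.default_rng(8)
        rows = []
        for q in range(30):
            ev = np.sort(10.0 ** rng.uniform(-12, 1, size=5))
            rows.extend(_hit_row(f"q{q}", e, sseqid=f"s{i}")
                        for i, e in enumerate(ev))
        hits = _hits(rows)
        loose, _ = assign_frames_homology(hits, 1e-2, "t")
        tight, _ = assign_frames_homology(hits, 1e-6, "t")
        assert set(tight) <= set(loose)


def _training_material(seed, usage=None, n=400, **over):
    cfg = SimulationConfig(seed=seed, n_contigs=n, coding_fraction=1.0,
                           adapter_rate=0.0, polya_rate=0.0, n_rate=0.0,
                           utr_length_range=(0, 0), **over)
    if usage is not None:
        cfg = dataclasses.replace(cfg, codon_usage=usage)
    contigs, truth = simulate_contigs(cfg)
    return cfg, {c.id: c.sequence for c in contigs}, \
        truth_calls(contigs, truth)


class TestCodonModel:
    def test_uniform_training_gives_flat_log_odds(self):
        """Codons drawn uniformly with a uniform background give flat
        log-odds across sense codons, up to sampling. The flat value is
        log(64/61), the structural offset from stop codons holding only
        pseudocount mass in stop-free training material."""
        rng = np.random.default_rng(4)
        sense = np.array([c for c in CODONS if c not in STOP_CODONS])
        seqs, calls = {}, {}
        for i in range(100):
            cid = f"t{i}"
            seqs[cid] = "".join(rng.choice(sense, size=6000))
            calls[cid] = FrameCall(cid, 1, "strict", "", 1e-9)
        model = train_codon_model(seqs, calls,
                                  background={b: 0.25 for b in "ACGT"})
        assert model.training_codons >= 50_000
        offset = math.log(64 / 61)
        assert max(abs(model.log_odds[c] - offset) for c in sense) <= 0.05

    def test_planted_skew_recovered(self):
        from ventannot.synthetic import joint_codon_frequencies
        cfg, seqs, calls = _training_material(5)
        model = train_codon_model(seqs, calls)
        assert model.training_codons >= 50_000
        est = model.codon_frequencies()
        planted = joint_codon_frequencies(cfg.codon_usage)
        assert sum(abs(est[c] - planted[c]) for c in est) <= 0.05

    def test_ambiguous_codon_excluded_from_training(self):
        seq = "ATG" + "GCT" * 50
        calls = {"a": FrameCall("a", 1, "strict", "", 1e-9)}
        base = train_codon_model({"a": seq}, calls)
        withn = train_codon_model({"a": seq[:30] + "ANT" + seq[33:]}, calls)
        assert withn.training_codons == base.training_codons - 1

    def test_untrainable_without_calls(self):
        with pytest.raises(TrainingError):
            train_codon_model({}, {})


@pytest.fixture(scope="module")
def model():
    _, seqs, calls = _training_material(9)
    return train_codon_model(seqs, calls)


class TestCodingScan:
    def test_planted_orf_frame_called(self, model):
        cfg = SimulationConfig(seed=21, n_contigs=1, coding_fraction=1.0,
                               adapter_rate=0.0, polya_rate=0.0, n_rate=0.0,
                               orf_codon_range=(150, 150))
        contigs, truth = simulate_contigs(cfg)
        c = contigs[0]
        call = scan_coding(c.id, c.sequence, model, score_threshold=0.0)
        assert call.tier == "scan"
        assert call.frame == truth.frames[c.id]

    def test_scan_matches_bruteforce_window_sum(self, model):
        """The scanner's (score, frame) equals an independent six-frame
        windowed-sum enumeration."""
        rng = np.random.default_rng(2)
        bases = np.array(list("ACGT"))
        for _ in range(20):
            seq = "".join(rng.choice(bases, size=int(rng.integers(120, 600))))
            score, frame, _ = _best_window(seq, model, 30)
            best = (-math.inf, 0)
            for fr in (1, 2, 3, -1, -2, -3):
                s = reverse_complement(seq) if fr < 0 else seq
                off = abs(fr) - 1
                codons = [s[i:i + 3] for i in range(off, len(s) - 2, 3)]
                window = []
                for c in codons + ["TAA"]:
                    if c in STOP_CODONS:
                        if len(window) >= 30:
                            s = sum(model.log_odds.get(x, 0.0)
                                    for x in window)
                            if s > best[0]:
                                best = (s, fr)
                        window = []
                    else:
                        window.append(c)
            assert best[1] == frame
            if frame != 0:
                assert best[0] == pytest.approx(score)

    def test_short_peptide_rejected(self, model):
        # 29-codon ORF in a 90-nt contig; TTA codons place stops across
        # the reverse strand, so no frame offers a 30-codon window
        seq = "ATG" + "TTA" * 28 + "TAA"
        call = scan_coding("x", seq, model, min_peptide=30,
                           score_threshold=-1e9)
        assert not call.assigned
        # the floor is what rejects it: lowering it admits a call
        assert scan_coding("x", seq, model, min_peptide=29,
                           score_threshold=-1e9).assigned

    def test_contig_shorter_than_peptide_floor_unassigned(self, model):
        call = scan_coding("x", "ATG" * 20, model, min_peptide=30,
                           score_threshold=-1e9)
        assert not call.assigned

    def test_masked_bases_carry_no_signal(self, model):
        cfg = SimulationConfig(seed=22, n_contigs=1, coding_fraction=1.0,
                               adapter_rate=0.0, polya_rate=0.0, n_rate=0.0,
                               orf_codon_range=(100, 100))
        contigs, _ = simulate_contigs(cfg)
        seq = contigs[0].sequence
        call_upper = scan_coding("x", seq, model, score_threshold=1.0)
        call_masked = scan_coding("x", seq.lower(), model,
                                  score_threshold=1.0)
        assert call_upper.assigned
        assert not call_masked.assigned


class TestCascade:
    def test_every_contig_in_exactly_one_bucket(self, small_bundle):
        contigs, _, hits = small_bundle
        seqs = {c.id: c.sequence for c in contigs}
        res = run_cascade(seqs, hits,
                          params=CascadeParams(null_sims=200, seed=7))
        tiers = {}
        for t in ("strict", "relaxed", "scan", "unassigned"):
            ids = {cid for cid, c in res.calls.items()
                   if (c.tier == t) or (t == "unassigned" and not c.assigned)}
            tiers[t] = ids
        union = set().union(*tiers.values())
        assert union == set(seqs)
        total = sum(len(v) for v in tiers.values())
        assert total == len(seqs)
        acc = res.accounting
        assert acc["total_translated"] == \
            acc["strict"] + acc["relaxed"] + acc["scan"]
        for cid, call in res.calls.items():
            assert bool(call.peptide) == call.assigned

    def test_no_hits_means_all_unassigned_with_warning(self):
        seqs = {"c1": "ACGT" * 50, "c2": "TTGCA" * 40}
        empty = pd.DataFrame(columns=HIT_COLUMNS)
        with pytest.warns(UserWarning, match="untrainable"):
            res = run_cascade(seqs, empty)
        assert all(not c.assigned for c in res.calls.values())
        assert res.accounting["unassigned"] == 2

    def test_invalid_cutoff_rejected(self, small_bundle):
        contigs, _, hits = small_bundle
        with pytest.raises(ConfigError):
            assign_frames_homology(hits, -1.0, "strict")


def test_null_threshold_is_reproducible_and_finite():
    _, seqs, calls = _training_material(9, n=50)
    model = train_codon_model(seqs, calls)
    t1 = calibrate_null_threshold(model, [400, 500], n_sims=100, seed=3)
    t2 = calibrate_null_threshold(model, [400, 500], n_sims=100, seed=3)
    assert t1 == t2 and math.isfinite(t1)
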