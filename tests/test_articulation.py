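import numpy as np
import pytest

from pthspeech import articulation as art
from pthspeech.errors import (
    AlignmentError,
    DegenerateAreaError,
    MissingClassError,
    UnknownPhoneError,
)
from pthspeech.prosody import phonetize
from pthspeech.segmentation import SpeechSegmentation
from pthspeech.synthetic_data import (
    VowelSpec,
    plan_for_prompt,
    synthesize_sentence,
    synthesize_vowel,
)

SENTENCE_1 = "The supermarket chain shut down because of poor management."


class TestFormants:
    @pytest.mark.parametrize("f1,f2,f3", [(700, 1200, 2400), (300, 2300, 3000)])
    @pytest.mark.parametrize("f0", [100.0, 140.0, 200.0])
    def test_synthesized_vowel_recovered_within_50hz(self, f1, f2, f3, f0):
        spec = VowelSpec(f0_hz=f0, formant_freqs_hz=(f1, f2, f3), duration_s=0.6)
        track = art.estimate_formants(synthesize_vowel(spec, 16000))
        assert track.valid.sum() >= 3
        assert np.median(track.f1_hz[track.valid]) == pytest.approx(f1, abs=50)
        assert np.median(track.f2_hz[track.valid]) == pytest.approx(f2, abs=50)

    def test_valid_frames_satisfy_f1_below_f2(self, vowel_700_1200):
        track = art.estimate_formants(vowel_700_1200)
        assert np.all(track.f1_hz[track.valid] < track.f2_hz[track.valid])


def _track_from_points(points):
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    return art.FormantTrack(
        times_s=np.arange(n) * 0.01,
        f1_hz=pts[:, 0],
        f2_hz=pts[:, 1],
        valid=np.ones(n, dtype=bool),
    )


class TestVowelSpaceArea:
    SEG = SpeechSegmentation(speech_intervals=((0.0, 10.0),), total_duration_s=10.0)
    TRIANGLE = [(300, 2300), (700, 1200), (300, 900)]

    def test_triangle_area_matches_shoelace(self):
        pts = self.TRIANGLE * 7  # alternating among the three vertices
        area = art.vowel_space_area(_track_from_points(pts), self.SEG)
        assert area == pytest.approx(280000.0)  # shoelace on the 3 vertices

    def test_identical_points_degenerate(self):
        with pytest.raises(DegenerateAreaError):
            art.vowel_space_area(_track_from_points([(500, 1500)] * 10), self.SEG)

    def test_area_invariant_to_frame_order_and_duplication(self):
        rng = np.random.default_rng(4)
        pts = rng.uniform([300, 800], [800, 2400], size=(40, 2))
        a1 = art.vowel_space_area(_track_from_points(pts), self.SEG)
        shuffled = pts[rng.permutation(40)]
        a2 = art.vowel_space_area(_track_from_points(shuffled), self.SEG)
        assert a1 == pytest.approx(a2)

    def test_area_grows_with_outside_point(self):
        base = [(400, 1000), (600, 1000), (500, 2000)] * 10
        a1 = art.vowel_space_area(_track_from_points(base), self.SEG)
        a2 = art.vowel_space_area(
            _track_from_points(base + [(900, 2500)] * 3), self.SEG
        )
        assert a2 >= a1


def _toy_model():
    # two 1-D phones well separated, unit variance
    return art.AcousticModel(
        means={"AA": np.array([0.0]), "S": np.array([10.0])},
        variances={"AA": np.array([1.0]), "S": np.array([1.0])},
        feature_dim=1,
    )


class TestGop:
    def test_intended_phone_is_maximizer_gives_zero(self):
        model = _toy_model()
        feats = np.zeros((5, 1))
        seg = art.PhoneSegment("AA", "vowel", 0.0, 0.05, 5, frame_slice=(0, 5))
        assert art.gop_score(seg, feats, model) == 0.0

    def test_hand_computed_ratio(self):
        # d=10, log L(intended)=-100, best competitor -90 -> GOP = -1.0
        class FixedModel:
            means = {"A": None, "B": None}

            def log_likelihood(self, phone, feats):
                return -100.0 if phone == "A" else -90.0

        seg = art.PhoneSegment("A", "vowel", 0.0, 0.1, 10, frame_slice=(0, 10))
        assert art.gop_score(seg, np.zeros((10, 1)), FixedModel()) == pytest.approx(-1.0)

    def test_gop_nonpositive_by_brute_force(self):
        rng = np.random.default_rng(5)
        model = art.AcousticModel(
            means={p: rng.normal(size=3) for p in "ABCD"},
            variances={p: rng.uniform(0.5, 2.0, size=3) for p in "ABCD"},
            feature_dim=3,
        )
        for trial in range(20):
            feats = rng.normal(scale=3.0, size=(4, 3))
            seg = art.PhoneSegment("A", "vowel", 0.0, 0.04, 4, frame_slice=(0, 4))
            score = art.gop_score(seg, feats, model)
            assert score <= 0.0
            # brute-force check of the ratio definition
            lls = {p: model.log_likelihood(p, feats) for p in "ABCD"}
            assert score == pytest.approx((lls["A"] - max(lls.values())) / 4)

    def test_score_decreases_away_from_intended_mean(self):
        model = _toy_model()
        seg = art.PhoneSegment("AA", "vowel", 0.0, 0.05, 5, frame_slice=(0, 5))
        scores = [
            art.gop_score(seg, np.full((5, 1), x), model) for x in np.linspace(5.0, 9.0, 9)
        ]
        assert all(b <= a for a, b in zip(scores, scores[1:]))

    def test_unknown_phone_errors(self):
        seg = art.PhoneSegment("ZZ", "vowel", 0.0, 0.05, 5, frame_slice=(0, 5))
        with pytest.raises(UnknownPhoneError):
            art.gop_score(seg, np.zeros((5, 1)), _toy_model())


class TestAlignment:
    def test_two_phone_boundary_recovered(self):
        model = _toy_model()
        k = 7
        feats = np.concatenate([np.zeros((k, 1)), np.full((12 - k, 1), 10.0)])
        times = np.arange(12) * 0.01
        segs = art.force_align(feats, times, ["AA", "S"], model)
        assert [s.phone_label for s in segs] == ["AA", "S"]
        assert abs(segs[0].frame_count - k) <= 1

    def test_single_phone_spans_all_frames(self):
        model = _toy_model()
        segs = art.force_align(np.zeros((9, 1)), np.arange(9) * 0.01, ["AA"], model)
        assert len(segs) == 1 and segs[0].frame_count == 9

    def test_segments_contiguous_and_in_prompt_order(self, acoustic_model):
        plan = plan_for_prompt(SENTENCE_1, speech_duration_s=4.01)
        audio, _, _ = synthesize_sentence(plan, 16000, seed=2)
        phones = [ph for w in SENTENCE_1.split() for ph in phonetize(w)]
        feats, times = art.mfcc_features(audio)
        segs = art.force_align(feats, times, phones, acoustic_model)
        assert [s.phone_label for s in segs] == phones
        for a, b in zip(segs, segs[1:]):
            assert b.frame_slice[0] == a.frame_slice[1]
        assert all(s.frame_count >= 1 for s in segs)

    def test_fewer_frames_than_phones_errors(self):
        with pytest.raises(AlignmentError):
            art.force_align(np.zeros((1, 1)), np.zeros(1), ["AA", "S"], _toy_model())


class TestPrecision:
    def _scored(self, labels_scores):
        return [
            art.PhoneSegment(lab, art.phone_class(lab), 0.0, 0.1, 1, (0, 1), gop=s)
            for lab, s in labels_scores
        ]

    def test_mean_over_class(self):
        segs = self._scored([("AA1", -1.0), ("IY1", -3.0), ("S", -5.0)])
        assert art.articulation_precision(segs, "vowel") == pytest.approx(-2.0)
        assert art.articulation_precision(segs, "consonant") == pytest.approx(-5.0)

    def test_all_zero_scores(self):
        segs = self._scored([("AA1", 0.0), ("S", 0.0)])
        assert art.articulation_precision(segs, "vowel") == 0.0

    def test_missing_class_errors(self):
        segs = self._scored([("S", -1.0)])
        with pytest.raises(MissingClassError):
            art.articulation_precision(segs, "vowel")

    def test_jittered_formants_score_lower_vowel_precision(self, acoustic_model):
        """Readings with 20%-jittered vowel formants are less precise."""
        scores = {}
        for jitter in (0.0, 0.2):
            plan = plan_for_prompt(
                SENTENCE_1, speech_duration_s=4.01, formant_jitter=jitter, jitter_seed=9
            )
            audio, _, _ = synthesize_sentence(plan, 16000, seed=5)
            phones = [ph for w in SENTENCE_1.split() for ph in phonetize(w)]
            feats, times = art.mfcc_features(audio)
            segs = art.force_align(feats, times, phones, acoustic_model)
            scored = [
                art.PhoneSegment(
                    **{**s.__dict__, "gop": art.gop_score(s, feats, acoustic_model)}
                )
                for s in segs
            ]
            scores[jitter] = art.articulation_precision(scored, "vowel")
        assert scores[0.2] < scores[0.0]
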