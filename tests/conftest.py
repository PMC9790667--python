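"""Shared fixtures: small synthetic subjects analysed once per session."""

import numpy as np
import pytest

import spindlespa as sp


@pytest.fixture(scope="session")
def symmetric_subject():
    """One symmetric (a=1 everywhere) subject, 360 s, fixed seed."""
    spec = sp.SubjectSpec(subject_id="SYM", duration_s=360.0, seed=11)
    return sp.synth_subject(spec)


@pytest.fixture(scope="session")
def symmetric_events(symmetric_subject):
    rec = sp.apply_filters(symmetric_subject.recording)
    bip = sp.extract_n2(rec, symmetric_subject.n2_segments)
    return sp.detect_spindles(bip)


@pytest.fixture(scope="session")
def co_asymmetric_subject():
    """Subject with amplitude factor 0.8 on the centro-occipital region."""
    spec = sp.SubjectSpec(subject_id="ASY", duration_s=360.0,
                          asymmetry={"CO": 0.8}, lesion_side="left", seed=12)
    return sp.synth_subject(spec)


@pytest.fixture(scope="session")
def small_cohort():
    """Six-subject cohort (2 UCP / 4 typical), short recordings, for
    pipeline-level tests."""
    spec = sp.CohortSpec(n_ucp=2, n_typical=4, master_seed=7,
                         subject_defaults=sp.SubjectSpec(duration_s=330.0))
    return sp.synth_cohort(spec)


def detection_scorecard(subject, events, region_map=None):
    """Recall/precision of detected events against ground truth, plus
    per-event frequency errors of matched pairs (overlap criterion)."""
    region_map = region_map or sp.REGION_MAP
    tp = fp = fn = 0
    freq_errors = []
    for region, (ld, rd) in region_map.items():
        true = [(g.onset_s, g.onset_s + g.duration_s, g.freq_hz)
                for g in subject.events if g.region == region]
        for deriv in (ld, rd):
            det = [e for e in events if e.derivation == deriv]
            matched = set()
            hit = 0
            for ts, te, f_true in true:
                for i, e in enumerate(det):
                    if i not in matched and e.onset_s < te and ts < e.offset_s:
                        matched.add(i)
                        hit += 1
                        freq_errors.append(abs(e.osc_freq_hz - f_true))
                        break
            tp += hit
            fn += len(true) - hit
            fp += len(det) - len(matched)
    return tp, fp, fn, freq_errors
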