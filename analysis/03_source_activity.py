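#!/usr/bin/env python
"""Estimate normalized eLORETA source activity and collapse to ROI x band.

Reads the EDF archive and the landmark table, builds the spherical-head
eLORETA operator, computes per-bin source power from sensor cross-spectra,
normalizes each solution by its grand mean over all voxels and 0.5-45 Hz
bins, and aggregates log10 mean normalized power into the six macro-ROIs
by eight individualized bands.  Writes results/activity.csv (one row per
subject x ROI x band).
"""

import argparse
import warnings
from pathlib import Path

import pandas as pd

from lewyeeg import edf, forward, inverse, spectral
from lewyeeg.montage import MONTAGE_10_10_30
from lewyeeg.recording import Recording
from lewyeeg.spectral import FrequencyLandmarks

parser = argparse.ArgumentParser()
parser.add_argument("--cohort", type=Path, default=Path("results/cohort"))
parser.add_argument("--landmarks", type=Path,
                    default=Path("results/landmarks.csv"))
parser.add_argument("--out", type=Path, default=Path("results"))
args = parser.parse_args()

lf, space = forward.load_leadfield(args.cohort / "leadfield")
op = inverse.eloreta_operator(lf)
print(f"eLORETA operator: {op.n_voxels} voxels, "
      f"{op.iterations} fixed-point iterations")

lms = pd.read_csv(args.landmarks).set_index("subject_id")
frames = []
excluded = []
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    for sid, row in lms.iterrows():
        lm = FrequencyLandmarks(sid, row["tf"], row["iaf"])
        if not lm.valid or lm.iaf - lm.tf < 1.0:
            excluded.append(sid)
            continue
        data, fs, labels = edf.read_edf(args.cohort / f"{sid}.edf")
        rec = Recording(sid, MONTAGE_10_10_30, fs, data, provenance="edf")
        std = spectral.standardize_recording(rec)
        eps = spectral.reject_epochs(spectral.epoch_recording(std))
        scheme = spectral.individual_band_scheme(lm)
        csd = inverse.sensor_cross_spectra(eps)
        src = inverse.normalize_solution(inverse.apply_inverse(csd, op))
        frames.append(inverse.collapse_band_roi(src, scheme, space).to_frame())

table = pd.concat(frames, ignore_index=True)
table.to_csv(args.out / "activity.csv", index=False)
print(f"wrote {table.subject_id.nunique()} subjects x 48 cells to "
      f"{args.out / 'activity.csv'}")
if excluded:
    print(f"excluded {len(excluded)} subject(s) with unusable landmarks: "
          f"{excluded}")
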