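"""Detect sleep from wrist movement and extract the 110 nightly features.

Runs the actigraphy-style detector (rolling SD of acceleration magnitude
below threshold, short gaps bridged) against the generator's known sleep
boundaries, then prints a few of the night's features.
"""

from migrasleep import (EffectSpec, SleepDetectorParams, SubjectProfile,
                        detect_sleep_period, extract_night_features,
                        generate_night, resample_channels,
                        segment_label_nights, generate_subject_dataset)

profile = SubjectProfile(
    subject_id="S1", n_days=4, n_migraine_days=1,
    sleep_duration_mean=1.5, sleep_duration_sd=0.1,
    sleep_onset_hour=23.5, sleep_onset_sd=0.1,
    wake_pad_hours=0.25, missing_night_prob=0.0,
)
params = SleepDetectorParams(min_sleep_s=3600.0)  # short synthetic nights

session, truth = generate_night(profile, False, EffectSpec.null(), seed=2,
                                return_truth=True)
block = resample_channels(session)
start, end = detect_sleep_period(block, params)
print(f"detected sleep: {(end - start) / 3600:.2f} h; boundary error "
      f"{abs(start - truth['sleep_start']) / 60:.1f} / "
      f"{abs(end - truth['sleep_end']) / 60:.1f} min vs ground truth")

sessions, diary = generate_subject_dataset(profile, EffectSpec.null(), seed=2)
nights = segment_label_nights(sessions, diary, params)
vec = extract_night_features(nights[0])
print(f"\nnight {vec.night_id} ({vec.label}): {len(vec.values)} features")
for name in ("mean_temp", "mean_hr", "std_eda", "qdiff_mean_temp",
             "corr_temp_eda", "hrv_rmssd", "hrv_nn50"):
    print(f"  {name:18s} {vec.as_dict()[name]: .4f}")
# mean_temp/mean_hr are the nocturnal levels the pre-migraine effect
# shifts; qdiff_mean_temp is the last-vs-first-quarter trend; hrv_rmssd is
# the time-domain heart-rate-variability index (seconds).
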