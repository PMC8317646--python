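"""Generate one synthetic stress-relax session and inspect its anatomy.

A session is three EEG recordings (MIST arithmetic stressor, VR
relaxation, final rest) of 4 frontal channels at 256 Hz, plus a latent
stress trajectory and the eight 1-5 survey answers that quantize it.
"""

import eegstress as es

schedule = es.build_default_schedule()
recordings, truth = es.simulate_session(schedule, es.SynthConfig(seed=0))

print(f"processed session: {schedule.total_duration_s:.0f} s -> {schedule.n_epochs} epochs of 2 s")
for rec in recordings:
    print(
        f"  {rec.phase:13s} raw {rec.duration_s:6.1f} s ({rec.n_samples} samples), "
        f"nominal {rec.nominal_duration_s:.0f} s, channels {', '.join(rec.channels)}"
    )
print("survey answers (T1..T8, SPSL 1-5):", truth.survey_answers.tolist())
print("latent stress range:", round(truth.trajectory.min(), 2), "->", round(truth.trajectory.max(), 2))
n_art = len(truth.session_artifact_epochs)
print(f"injected artifact epochs (> 75 uV bursts): {n_art} of {schedule.n_epochs}")
# Raw durations jitter by a few seconds (onsets are 'marked manually');
# resampling in the preprocessing stage restores the nominal lengths.
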