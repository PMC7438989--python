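"""Extract the six electrophysiological features from one recording.

Builds a synthetic bursty neuron (3.3 Hz, 38% of spikes in bursts, 3.0 ms
AP with a notch on the rising phase) and runs the feature extractor on it.
"""

from vtaclust import RecordingSession, extract_features
from vtaclust.synthetic import generate_spike_train, generate_waveform

train, truth = generate_spike_train(3.3, 38.0, rng=1, neuron_id="demo")
waveform = generate_waveform(3.00, 1.11, notch=True, notch_phase="rise",
                             noise_sd=0.01, rng=1, neuron_id="demo")
fv = extract_features(RecordingSession(train, waveform))

print(f"firing rate : {fv.firing_rate:6.2f} Hz    (target 3.3)")
print(f"rate CV     : {fv.cv:6.3f}       (binned-rate regularity index)")
print(f"%SIB        : {fv.pct_sib:6.2f} %     (constructed {truth.pct_sib:.2f})")
print(f"AP duration : {fv.ap_duration:6.2f} ms    (target 3.00)")
print(f"delta-t1    : {fv.dt1:6.2f} ms    (target 1.11)")
print(f"notch       : {fv.notch}           (injected on the rise)")
print()
print("The %SIB equals the constructed ground truth exactly: the generator's")
print("event process realizes the 80/160 ms burst rule by construction.")
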