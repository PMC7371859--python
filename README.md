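# entrain

Analysis toolkit for rhythmic-TMS/EEG entrainment experiments: stimulation
protocol generation, TMS-EEG artifact removal, phase-locking-value (PLV)
quantification, cluster-based permutation statistics, and a synthetic-data
generator with ground truth so the whole pipeline is testable end to end
without any recorded data.

## What is in the box

| module | purpose |
| --- | --- |
| `entrain.core_io` | `Recording`/`Event` data model, BrainVision and EDF readers/writers, neighbor graphs |
| `entrain.montage` | idealized 64-channel 10-10 sensor template, channel-set helpers |
| `entrain.synth` | ground-truth EEG generator: posterior alpha oscillator over 1/f noise, tunable pulse-train coupling (von Mises kappa), ringing/decay artifacts, blinks, bad channels, phantom and resting variants |
| `entrain.protocol` | rhythmic/arrhythmic/sham pulse schedules with forbidden-frequency constraints, electric-field dose arithmetic and percentile summaries |
| `entrain.preprocess` | artifact cascade: segmentation, ringing excision, decay-component ICA, pchip interpolation, common-average re-reference + downsampling, IQR/STD/correlation rejection, ocular ICA |
| `entrain.spectral` | individual alpha frequency (IAF) estimation via multitaper spectra with eyes-closed fallback |
| `entrain.plv` | offset-aligned reference wave, Morlet phase extraction, PLV, relative baseline normalization, pulse-locked PLV |
| `entrain.stats` | dependent/independent cluster-based permutation tests over electrodes |
| `entrain.pipeline` | end-to-end synthetic study (`run_main`) and phantom / simulated-marker controls (`run_controls`) |

## CLI

The console script `entrain` exposes the main operations:

```bash
entrain protocol make --iaf 10 --blocks 5 --bursts 25 --out schedule.json
entrain synth session --seed 1 --out data/           # BrainVision triplet
entrain synth resting --seed 1 --duration 240 --eyes closed --out data/
entrain iaf --open data/open --closed data/closed --out iaf.json
entrain preprocess --in data/session --out trials/
entrain stats cluster --a a.csv --b b.csv --paired --nperm 1000 --seed 1
entrain dose ef2mso --target 20 --slope 2.105
entrain dose summarize --in ef_values.csv
entrain run main --config study.yaml --out report/
entrain io convert --in data/session --out data/session_edf --dialect edf
```

## Marker dialect (format appendix)

BrainVision `.vmrk` stimulus markers use `S<code>` descriptions with
`code = kind + condition`, where kind is 1 (pulse), 10 (burst onset),
20 (burst offset), 30 (block start), 40 (block end) and condition adds
0 (none), 100 (rhythmic), 200 (arrhythmic) or 300 (sham).  The marker
channel field carries `burst_index + 1`.  Unknown descriptions are read
back as `kind='none'` with a warning.  EDF files carry their events in a
`<stem>.events.json` sidecar because base EDF has no marker track.

## Conventions

- all signal amplitudes in microvolts; time in seconds with t = 0 at the
  first sample of a recording; trial time is relative to the burst offset
  (t = 0 at the last pulse);
- burst duration follows the n/f convention (20 pulses at 8 Hz = 2.5 s);
- percentiles use linear interpolation between order statistics;
- every generator and statistical routine is deterministic per seed.
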