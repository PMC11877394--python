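# tempocode

A simulation toolkit for time-domain, signal-centric neural computation:

- **`core_signals`** — waveforms, spike trains, phase-locked encoding
  (zero-crossing / peak), first- and all-order interspike-interval
  histograms, pooled population-interval distributions, and
  autocorrelation-style F0 estimation (including missing-fundamental
  recovery through a minimal band-pass channel bank).
- **`interference`** — delay-and-sum superposition of signal pathways,
  constructive/destructive interference, steady-state amplitude,
  relative phase and spectral coherence measurement.
- **`timing_nets`** — coincidence detection across spike trains,
  Jeffress-style internal-delay estimation over tapped delay lines,
  reverberatory loop strength dynamics (`gain^k` with saturation), and
  coincidence-driven path facilitation.
- **`holomem`** — holographic associative memory on fixed-dimension real
  vectors: binding by circular convolution, recall by circular
  correlation, superposed traces, content-addressable cleanup, sequence
  completion, and graceful degradation of damaged traces.
- **`cascade`** — single-sideband carrier-suppressed (SSBCS) heterodyne
  mixing: pointwise multiplicative mixing, difference-band selection by
  linear-phase FIR low-pass, chained mixing cascades with emergent
  carrier measurement and suppression reporting, and amplitude-envelope
  transport/recovery across stages.
- **`fixtures` / `io` / `cli`** — deterministic synthetic input
  generation, plain-text/WAV/CSV/JSON formats, and a `tempocode` CLI.

## CLI

```sh
# synthesize a tone, encode it, estimate its fundamental
tempocode fixture --kind pure_tone --hz 100 --duration 1 --out tone.wav
tempocode encode tone.wav --mode zero-crossing --out spikes.txt
tempocode f0 spikes.txt

# run the seven-stage SSBCS mixing cascade and write a stage report
tempocode cascade --start-hz 180 --lo-hz 90,45,24,10,6,2.5,1.5 \
    --duration 40 --report cascade.json
# named oscillation bands work too:
tempocode cascade --start-hz 180 --lo-hz high_gamma,gamma,beta --duration 20

# holographic memory
tempocode holomem store --labels a,b,c,d --mode sequence --seed 3 --out mem
tempocode holomem sequence --memory mem --cue a -k 3

# timing networks
tempocode timingnet jeffress left.txt right.txt --taps 0,0.001,0.002,0.003
tempocode timingnet reverberate spikes.txt --gain 0.8 --cycles 5
```

Subcommands exit 2 on usage errors and 1 on rejected inputs or
configurations. All stochastic commands take `--seed` and produce
byte-identical outputs for a fixed seed.

## Conventions

Times are seconds, frequencies Hz, everywhere. Spike-train text files
hold one spike time per line with an optional `duration=<s>` header and
`#` comments. Waveforms are WAV (float32) or two-column CSV
(`time_s,amplitude`). Holographic memories serialize as a CSV of
vectors plus a JSON sidecar (labels, dimension, binding count, seed).
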