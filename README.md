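# audiosim

A desk-scale simulator and analysis engine for **automated speech
audiometry** in quiet and in noise.

Speech audiometry measures how well a patient understands speech: short
phonetically balanced words are played at varying presentation levels (in
quiet, dB HL) or signal-to-noise ratios (in noise, dB SNR), the patient
repeats what they heard, and each repeated phoneme is scored correct or
not. The resulting **psychometric function** — intelligibility (%) versus
level or SNR — is summarized by the **speech reception threshold** (SRT,
the level/SNR at 50% intelligibility), the **maximum intelligibility**,
and the **slope at the 50% point** (%/dB). Clinically these tests are run
with an adaptive level-selection procedure and scored live, either
manually by a hearing expert or automatically by a phoneme-level speech
recognizer.

`audiosim` reproduces this whole measurement chain *in silico* so that
the automated procedures, scoring rules and analysis pipeline can be
studied, validated and stress-tested without patients or audio:

- **materials** — synthetic phonetically balanced word lists with the
  clinical structure (20 lists × 17 words × 3 phonemes in quiet; 5
  logatom lists × 17 × 3 in noise), with a total-variation balance
  metric;
- **listener** — a virtual patient: an audiogram, a four-parameter
  logistic psychometric function p(x) = floor + (ceiling − floor)/(1 +
  e^(−k(x−x₀))) parameterized by SRT and slope, and per-phoneme Bernoulli
  responses with configurable confusion behaviour;
- **scoring** — a perfect "manual expert" scorer and a noisy
  ASR-emulating scorer with per-phoneme error rates calibrated to a
  clinical recognizer's pre-validation performance (phoneme accuracy
  0.979 on correct repetitions, phoneme error rate 0.174 on incorrect
  ones, for the quiet material), plus minimum-edit-distance phoneme
  alignment with `UNKNOWN`/`BLANK` token semantics;
- **procedures** — the adaptive speech-in-quiet test (initial level from
  the pure-tone average, descending/ascending 10 dB staircase, 5 dB steps
  above 80 dB HL, early stop after 7 words below 15% with 0% imputation,
  derivative-reversal stop) and the speech-in-noise test (speech fixed at
  60 dB SPL, SNR ladder with separate orders for normal-hearing and
  hearing-impaired listeners);
- **psychometrics** — SRT, maximum intelligibility and slope extraction
  by monotonized linear interpolation or logistic fitting;
- **analysis** — automated-vs-manual raw/absolute differences,
  word-by-word convergence profiles, and test–retest reliability tables.

## Worked example

Simulate one hearing-impaired ear (PTA 40 dB HL, true SRT 50 dB HL,
slope 5 %/dB) through the adaptive speech-in-quiet test, scored in
parallel by the manual-equivalent oracle and the calibrated ASR emulator:

```python
import audiosim as a
from audiosim.listener import flat_audiogram

material = a.generate_material("quiet", n_lists=20, words_per_list=17,
                               phonemes_per_word=3, seed=1)
profile = a.ListenerProfile(
    audiogram=flat_audiogram(40.0), axis="level_dB_HL",
    srt=50.0, slope50=5.0, listener_id="patient-01",
)
scorers = {
    "oracle": a.OracleScorer(),
    "asr": a.ASRScorer(a.ScorerConfig.from_prevalidation("quiet"),
                       material.inventory),
}
session = a.run_quiet_procedure(material, profile, scorers, seed=7)
for p in session.points["oracle"]:
    print(f"{p.x:5.0f} dB HL  {p.pct:6.1f} %  ({p.provenance})")
for name in ("oracle", "asr"):
    s = a.summarize(session.points[name])
    print(f"{name:6s} SRT = {s.srt50:.1f} dB HL, "
          f"max = {s.max_intelligibility:.1f} %, "
          f"slope = {s.slope50:.1f} %/dB")
```

prints

```
   30 dB HL     0.0 %  (imputed_zero)
   40 dB HL     9.5 %  (early_stopped)
   50 dB HL    56.9 %  (measured)
   60 dB HL    96.1 %  (measured)
   70 dB HL    98.0 %  (measured)
   80 dB HL   100.0 %  (measured)
oracle SRT = 48.6 dB HL, max = 100.0 %, slope = 4.7 %/dB
asr    SRT = 48.9 dB HL, max = 100.0 %, slope = 4.5 %/dB
```

The procedure started at PTA + 20 = 60 dB HL, descended by 10 dB until
the 40 dB list stopped early (score below 15% after 7 words), imputed
30 dB as 0% without testing, then ascended until 100% was reached. Both
scorers saw the same responses, so the 0.3 dB SRT disagreement is due
purely to the ASR's transcription noise — the kind of difference the
analysis module aggregates into raw/absolute comparison tables.

### Command line

```bash
audiosim generate-material --kind quiet --seed 1 --out material.json
audiosim simulate --mode quiet --material material.json \
    --listener listener.yaml --scorers oracle,asr --seed 2 --out session.json
audiosim analyze --sessions session.json --out tables/
audiosim cohort --seed 3 --out run/          # full generate→simulate→analyze
audiosim retest --seed 3 --out run-retest/   # every listener tested twice
```

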