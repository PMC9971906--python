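# curtainkit

Single-molecule DNA-curtain analysis in Python: a ground-truthed synthetic
imaging simulator plus the full measurement pipeline — subpixel 2D-Gaussian
PSF localization, fiducial drift correction, trajectory linking across
quantum-dot blinking gaps, px→bp calibration, resection kinetics (velocity,
processivity, pause detection, dwell-time survival fits), and cohort-level
statistics (initiation / colocalization fractions with bootstrap SDs,
t tests, fold changes, GC-content associations).

## Modules

| module | what it does |
|---|---|
| `curtainkit.simulate` | synthetic curtain movies: motors with pauses/dissociation on 48.5 kb tethers, two-state QD blinking, stage drift, flow-stop recoil, EMCCD noise; every stack ships with a per-frame ground-truth table |
| `curtainkit.localize` | spot detection (MAD noise floor), integrated-Gaussian PSF fits with analytic Jacobian, fiducial drift estimation/subtraction |
| `curtainkit.track` | greedy nearest-neighbor linking with gap closing, tether calibration, flow-stop (DNA-bound vs surface-stuck) and 1 kb movement filters |
| `curtainkit.kinetics` | per-molecule velocity (OLS), processivity, sliding-window pause detector (500 bp / 30 s defaults), Kaplan–Meier + exponential survival fits, dissociation fractions |
| `curtainkit.cohort` | initiation/colocalization fractions with bootstrap SDs, Welch/Student t tests with significance stars, fold changes, GC profile and pause–GC association |
| `curtainkit.pipeline` | JSON-config orchestration with per-run manifests (seeds, hashes, molecule counts at each filter) |

## CLI

```bash
curtainkit simulate --out sim/ --seed 1                 # fixture battery
curtainkit localize --stack sim/stack_ch0.tif \
    --fiducial-roi 2,2,8,8 --out det.csv
curtainkit track --detections det.csv --calibration cal.json \
    --flow-stop 10:25 --out traj.csv
curtainkit analyze --traj traj.csv --pause-min 30 --resolution 500 --out kin/
curtainkit stats --kinetics kin/kinetics.csv --out summary.json
curtainkit run --config cfg.json --out run/ --seed 1    # all stages, one config
```

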