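# mitoholo

Analysis pipeline for a label-free assay of the **mitochondrial
permeability transition** (PT) in living cells, combining holographic
refractive-index (RI) imaging with TMRM fluorescence.

Opening of the high-conductance permeability transition pore (PTP)
equilibrates solutes up to ~1.5 kDa between the mitochondrial matrix and
the cytosol. That equalizes their refractive indices, so a permeabilized
mitochondrion *disappears* from the RI image — a direct, dye-free readout
of permeabilization. Recording TMRM simultaneously separates two events
that fluorescence alone conflates:

* **depolarization** — the normalized TMRM trace F_norm(t) of an organelle
  falls below baseline;
* **permeabilization** — the organelle's area in the binary RI
  segmentation collapses to zero.

The per-organelle statistics the pipeline produces are the **residual
potential** (F_norm at the frame the organelle vanishes; ≈ 15% of baseline
in wild-type cells) and the **delay** between depolarization onset and
disappearance (≈ 150 s) — the quantitative signature that depolarization
*precedes* high-conductance PTP opening. TMRM traces are anchored by the
FCCP addition at the end of every recording:

    F_norm(t) = (F(t) − F̄_FCCP) / (F̄_baseline − F̄_FCCP)

The package is aimed at anyone quantifying dual-channel (RI + potential)
organelle time-lapse data, and ships a forward simulator with analytic
ground truth covering the assay's four condition archetypes: wild type +
ferutinin (calcium ionophore; depolarization then permeabilization),
+ cyclosporin A (both blocked), FCCP only (depolarization without
permeabilization), and ATP-synthase/ANT-knockout + ferutinin (lower basal
potential, depolarization, no permeabilization).

## Layout

    src/mitoholo/      library: simkit, stacks_io, segmentation, quantify,
                       track_events, stats_report, pipeline, cli
    analysis/          numbered drivers: 01_simulate.py -> 02_analyze.py -> 03_report.py
    scripts/           acceptance.py (see "Reproducing the results")
    tests/             pytest suite
    docs/methods.md    model, parameters, design choices, limitations

## Worked example

```python
from mitoholo import simkit, pipeline

scenario = simkit.make_scenario("WT_FERUTININ", n_mito=10, seed=1)
result, truth = pipeline.simulate_and_analyze(scenario)

events = result.events_frame().dropna(subset=["onset_s", "perm_s"])
print(f"tracked organelles:        {len(result.tracks)}")
print(f"permeabilization events:   {events['perm_s'].notna().sum()}")
print(f"mean residual potential:   {events['residual_potential'].mean():.3f}"
      f"  (generator truth {truth.organelles[0].residual_fraction:.2f})")
print(f"mean onset-to-perm delay:  {events['delay_s'].mean():.1f} s"
      f"  (generator truth {truth.to_frame()['delay_s'].mean():.1f} s)")
```

prints

    tracked organelles:        10
    permeabilization events:   10
    mean residual potential:   0.126  (generator truth 0.15)
    mean onset-to-perm delay:  150.0 s  (generator truth 150.0 s)

All ten simulated organelles are tracked in the RI channel and each gets
both events. The measured residual potential sits slightly below the
generating threshold of 0.15 because events are quantized to the 15 s
frame grid and an organelle is detected as gone shortly *after* the
continuous trigger; the onset and permeabilization detection latencies
largely cancel in the delay. `docs/methods.md` discusses both biases.

The same chain runs from the shell on TIFF movies (simulated or real):

    mitoholo simulate --condition WT_FERUTININ --seed 1 --outdir movie/
    mitoholo analyze --ri movie/ri.tif --tmrm movie/tmrm.tif \
        --metadata movie/metadata.yaml --outdir analyzed/
    mitoholo report --analyzed analyzed/ --outdir report/

`analysis/01_simulate.py` → `02_analyze.py` → `03_report.py` run a small
multi-condition study end to end, writing tables under `results/`.

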