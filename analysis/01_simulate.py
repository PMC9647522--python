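"""Simulate the four condition archetypes as dual-channel TIFF movies.

Writes, for each condition and replicate, an experiment directory under
scratch/movies/ containing ri.tif, tmrm.tif, metadata.yaml and
ground_truth.csv, plus a manifest table under results/ listing every
simulated experiment. Downstream: 02_analyze.py.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from mitoholo import simkit

ROOT = Path(__file__).resolve().parents[1]
MOVIE_DIR = ROOT / "scratch" / "movies"
RESULTS = ROOT / "results"

CONDITIONS = simkit.CONDITIONS
N_REPLICATES = 3
BASE_SEED = 2026


def main() -> None:
    rng = np.random.default_rng(BASE_SEED)
    rows = []
    for condition in CONDITIONS:
        for rep in range(N_REPLICATES):
            seed = int(rng.integers(0, 2**31 - 1))
            scenario = simkit.make_scenario(condition, n_mito=10, seed=seed)
            outdir = MOVIE_DIR / f"{condition}_{rep:02d}"
            paths = simkit.write_experiment(scenario, outdir)
            gt = pd.read_csv(paths["ground_truth"])
            rows.append(
                dict(
                    condition=condition,
                    replicate=rep,
                    seed=seed,
                    directory=str(outdir.relative_to(ROOT)),
                    n_mito=scenario.n_mito,
                    n_perm_events=int(gt["perm_s"].notna().sum()),
                )
            )
            print(f"{condition} rep {rep}: seed {seed}, "
                  f"{rows[-1]['n_perm_events']} ground-truth permeabilization events")
    RESULTS.mkdir(exist_ok=True)
    manifest = pd.DataFrame(rows)
    manifest.to_csv(RESULTS / "simulated_manifest.csv", index=False)
    print(f"\n{len(manifest)} movies under {MOVIE_DIR}; manifest -> results/simulated_manifest.csv")


if __name__ == "__main__":
    main()
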