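"""Simulate the study session: 100 units, four tasks (EXE, OBSb, OBSnb,
NOGO), 10 correct trials per task×object condition, with the
format-hypothesis latent structure — the OBSnb loading plane coincides with
OBSb's, EXE's is orthogonal to both, NOGO overlaps OBSb at 0.25.

Writes spikes.csv / trials.csv / units.csv and the generator's ground truth
(loadings, achieved overlaps) under results/data/.
"""

import json

import mirrorpop as mp
from _common import DATA_DIR, N_UNITS, SESSION_SEED


def main() -> None:
    spec = mp.LatentSpec(n_units=N_UNITS, seed=SESSION_SEED)
    ds = mp.generate_dataset(spec)
    mp.write_dataset(ds, DATA_DIR)
    gt = mp.write_ground_truth(spec, DATA_DIR)
    truth = json.loads(gt.read_text())
    print(f"simulated {len(ds.units)} units, {len(ds.trials)} trials, "
          f"{len(ds.spikes)} spikes -> {DATA_DIR}")
    print("achieved plane overlaps vs OBSb:",
          {k: round(v, 3) for k, v in truth["achieved_overlap"].items()})


if __name__ == "__main__":
    main()
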