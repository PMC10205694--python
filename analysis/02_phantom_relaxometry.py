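#!/usr/bin/env python
"""Phantom imaging pipeline: simulate, fit maps, extract NP, compare to truth.

Builds the five-disc spin-lock phantom at SNR 50, writes it as NIfTI,
runs relaxometry -> inertia-tensor standardization -> central-AP-40% NP
extraction -> per-disc biomarkers, and reports the recovery error of
each disc's planted NP mean.  Outputs under results/phantom/.
"""

import json
from pathlib import Path

from discqmri import synthetic as syn
from discqmri.config import RunConfig
from discqmri.pipeline import run_phantom_pipeline, simulate_phantom_inputs

ROOT = Path(__file__).resolve().parents[1] / "results" / "phantom"
SEED = 7


def main() -> None:
    spec = syn.PhantomSpec()
    info = simulate_phantom_inputs(ROOT / "inputs", spec=spec, seed=SEED)
    cfg = RunConfig(noise_sigma=spec.sigma, seed=SEED)
    table = run_phantom_pipeline(ROOT / "inputs", ROOT / "outputs", cfg)

    truth = info["truth"]["np_true_means_t1rho"]
    table["np_true"] = table["level"].map(truth)
    table["error_ms"] = table["np_t1rho_mean"] - table["np_true"]
    cols = ["level", "np_t1rho_mean", "np_true", "error_ms", "n_valid_voxels"]
    print(table[cols].round(2).to_string(index=False))
    print(f"max |NP recovery error| = {table['error_ms'].abs().max():.2f} ms "
          f"(SNR {spec.snr:g}, {len(table)} discs)")
    (ROOT / "recovery.json").write_text(
        json.dumps(table[cols].round(4).to_dict(orient="records"), indent=2)
    )


if __name__ == "__main__":
    main()
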