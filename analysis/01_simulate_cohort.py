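#!/usr/bin/env python
"""Generate the default synthetic cohort and write its tables.

Emulates the study design: 133 subjects (80 cLBP / 53 control, 61 F /
72 M, ages truncated-normal with mean 43.9 y), five lumbar levels with
L1-L2 missing for 15 subjects, per-disc NP-T1rho/NP-T2 biomarkers with
the published effect sizes planted, Pfirrmann grades, and a per-voxel
NP table.  Outputs: results/cohort/{subjects,discs,voxels}.csv.
"""

from pathlib import Path

from discqmri import synthetic as syn

OUT = Path(__file__).resolve().parents[1] / "results" / "cohort"
SEED = 20230101


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    subjects, discs = syn.generate_cohort(seed=SEED)
    voxels = syn.generate_voxels(discs, seed=SEED)
    subjects.to_csv(OUT / "subjects.csv", index=False)
    discs.to_csv(OUT / "discs.csv", index=False)
    voxels.to_csv(OUT / "voxels.csv", index=False)

    print(f"subjects: {len(subjects)} ({(subjects.group == 'cLBP').sum()} cLBP, "
          f"{(subjects.sex == 'F').sum()} F); mean age {subjects.age.mean():.1f} y")
    print(f"disc records: {len(discs)}; NP voxels: {len(voxels)}")
    means = discs.groupby("group")["np_t1rho_mean"].agg(["mean", "std"]).round(1)
    print("NP-T1rho by group (ms):")
    print(means.to_string())
    print(f"tables written to {OUT}")


if __name__ == "__main__":
    main()
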