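"""Generate the paired phantom cohort used by all downstream analyses.

Writes 8 subjects x (1 real CT + 2 synthetic CTs + 7 masks) as NIfTI under
scratch/cohort (volumes are bulky; tables and figures go to results/), plus
the JSON manifest the later steps read.
"""

import json
from dataclasses import asdict
from pathlib import Path

import sctradiomics as s
from sctradiomics.io import write_cohort

ROOT = Path(__file__).resolve().parents[1]
COHORT_DIR = ROOT / "scratch" / "cohort"
SEED = 42
N_SUBJECTS = 8


def main():
    spec = s.PhantomSpec()
    degradations = s.default_degradations()
    cohort = s.generate_cohort(N_SUBJECTS, spec, degradations, master_seed=SEED)
    manifest = write_cohort(cohort, COHORT_DIR)
    provenance = {
        "seed": SEED,
        "n_subjects": N_SUBJECTS,
        "phantom_spec": asdict(spec),
        "degradations": [asdict(d) for d in degradations],
    }
    (COHORT_DIR / "provenance.json").write_text(
        json.dumps(provenance, indent=2, default=str)
    )
    n_vols = sum(1 + len(c.synthetic) for c in cohort.cases)
    print(f"wrote {N_SUBJECTS} subjects ({n_vols} volumes, "
          f"{len(cohort.roi_names)} ROIs each) to {COHORT_DIR}")
    print(f"manifest: {manifest}")
    frac = __import__("sctradiomics.synthetic", fromlist=["gtv_class_fractions"])
    air, soft, bone = frac.gtv_class_fractions(cohort.cases[0], spec)
    print(f"subject 0 tumor composition: air {air:.1%}, soft {soft:.1%}, bone {bone:.1%}")


if __name__ == "__main__":
    main()
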