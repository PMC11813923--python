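"""Build an augmented p-rep trial layout and check series connectivity.

Generates one 14x10 trial (80 unreplicated entries, 15 duplicated
checks, 5 six-fold standards = 140 plots, 100 accessions), then the full
nine-trial series, and reports how many genotypes every pair of trials
shares — the common checks are what make cross-trial genotype
comparisons identifiable.
"""

from megaenv import (TrialSpec, build_augmented_prep_layout,
                     check_connectivity)
from megaenv.simulate import study_trial_specs


def ids(prefix, n):
    return [f"{prefix}{i:03d}" for i in range(n)]


spec = TrialSpec("AG18", n_single=80, n_dup_checks=15, n_standards=5,
                 grid_rows=14, grid_cols=10, seed=1)
design = build_augmented_prep_layout(spec, ids("E", 80), ids("C", 15),
                                     ids("S", 5))
print(f"trial {spec.trial_id}: {len(design.assignment)} plots, "
      f"{len(design.genotypes)} distinct accessions")
print(design.to_frame().head(6).to_string(index=False))

checks, standards = ids("C", 15), ids("S", 5)
series = [build_augmented_prep_layout(s, ids(f"T{k}E", s.n_single),
                                      checks, standards)
          for k, s in enumerate(study_trial_specs(seed=1))]
report = check_connectivity(series)
print(f"\nnine-trial series connected: {report.connected}; "
      f"minimum pairwise overlap {report.min_overlap} genotypes")
print("(every pair of trials shares at least the 20 replicated "
      "checks/standards, so the whole series forms one connected design)")
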