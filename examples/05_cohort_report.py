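"""Small synthetic cohort: donor summaries, box-plot statistics and
correlation with reference (hematology-analyzer-style) counts."""

import dataclasses

import pandas as pd

import evcounter as ev
from evcounter.plotting import cohort_boxplot

base = ev.whole_blood_sample(seed=13)
conc = {"leukocyte": 1500.0, "RBC": 2000.0, "platelet": 1200.0, "ldEV": 500.0}
pops = tuple(dataclasses.replace(p, concentration=conc[p.class_name],
                                 suspended=False)
             for p in base.populations)
cfg = dataclasses.replace(base, populations=pops, frames_per_well=8)
optics = ev.OpticsConfig(frame_shape=(256, 256), defocus_sigma_range=(0.0, 0.0))

run = ev.run_cohort(cfg, n_donors=4, wells_per_donor=4, optics=optics)
pd.set_option("display.width", 120)
print(run.donor_summary.round(2).to_string(index=False))
print()
print(run.cohort_summary.round(2).to_string(index=False))

# correlate imaging counts against the ground truth as an analyzer-style
# reference (per-donor true counts, extrapolated to 1 uL)
truth = pd.DataFrame(run.truth_counts)
ref = (truth.groupby("donor_id")[list(conc)].mean() / 0.02).reset_index() \
    .melt(id_vars="donor_id", var_name="class", value_name="per_ul")
fits = ev.correlation_report(run.donor_summary, ref)
for cls, fit in fits.items():
    print(f"{cls}: slope {fit.slope:.2f}, R^2 {fit.r_squared:.2f}, "
          f"imaging/reference {fit.underestimation_factor:.2f}")

ax = cohort_boxplot(run.cohort_summary)
ax.figure.savefig("scratch_cohort_boxplot.png", dpi=120)
print("box plot written to scratch_cohort_boxplot.png")
# per_7p5ml extrapolates each 0.02 uL well to a 7.5 mL draw; whiskers are
# Q1-1.5*IQR and Q3+1.5*IQR over donors.
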