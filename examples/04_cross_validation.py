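"""Repeated k-fold cross-validation on a planted world, with a null control.

Runs a scaled-down protocol (1 repeat x 5 folds x 3 negative draws) on the
planted world and on a shuffled-label null, printing AUC/AUPR/F1 for both.
"""

from hypermir.io import Config
from hypermir.synthetic import generate_world, shuffle_associations
from hypermir.train_eval import run_cv

world = generate_world(M=60, D=40, r=4, density_target=0.1,
                       noise_sd=0.05, seed=3)
cfg = Config(epochs=300, seed=3, n_repeats=1, n_folds=5, n_neg_draws=3)

report = run_cv(world.T, cfg, mirna_sim=world.sim_m, disease_sim=world.sim_d)
s = report.summary()
print(f"planted world : AUC {s['auc_mean']:.3f} +/- {s['auc_std']:.3f}   "
      f"AUPR {s['aupr_mean']:.3f}   F1 {s['f1_mean']:.3f}")

null = shuffle_associations(world, seed=103)
null_report = run_cv(null.T, cfg, mirna_sim=null.sim_m,
                     disease_sim=null.sim_d)
ns = null_report.summary()
print(f"shuffled null : AUC {ns['auc_mean']:.3f} +/- {ns['auc_std']:.3f}   "
      f"AUPR {ns['aupr_mean']:.3f}   F1 {ns['f1_mean']:.3f}")
print("Masked associations are ranked far above sampled negatives on the "
      "planted world; shuffling the labels pushes AUC back to ~0.5.")
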