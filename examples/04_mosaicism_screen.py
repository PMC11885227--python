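"""Flag confined placental mosaicism among aneuploidy-positive samples.

Full trisomies imply a fetal fraction (AneuFC) that agrees with the chrY
estimate; when only part of the placenta is aneuploid the dosage signal is
diluted and the combined Z-score against a full-trisomy reference flags the
discordance.
"""

import numpy as np

import cfnipt as cf
from cfnipt.mosaicism_screen import FFTriple

genome = cf.default_genome()
rng = np.random.default_rng(23)
f_exp, kappa = genome.aneufc_calibration("chr1")
background = genome.dosage_background("chr1")
calib = genome.chry_calibration()


def triple(ff, m, sid):
    frags, meta = cf.simulate_sample(genome, ff, "male",
                                     cf.Karyotype("chr1", m), "control",
                                     200_000, rng, sample_id=sid)
    sex = cf.estimate_ff_chry(frags, meta, calib)
    aneu = cf.estimate_aneufc(frags, "chr1", f_exp, background, kappa)
    return FFTriple(sid, sex, None, aneu)


reference = [triple(float(rng.uniform(0.05, 0.20)), 1.0, f"REF{i}")
             for i in range(60)]
tests = [triple(0.15, 1.0, "full_trisomy"),
         triple(0.15, 0.5, "cpm_m_0.5"),
         triple(0.15, 0.25, "cpm_m_0.25")]

print("sample         sexFC  AneuFC      D      z  flagged")
for call, t in zip(cf.combined_zscore(tests, reference), tests):
    print(f"{t.sample_id:13s} {t.sexFC:6.3f}  {t.AneuFC:6.3f} "
          f"{call.discordance:6.3f} {call.combined_z:6.1f}  {call.flagged}")
# AneuFC ~ m * ff: the full trisomy is concordant (z ~ 0); the mosaics show
# discordance ff*(1-m) and are flagged at z > 3.
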