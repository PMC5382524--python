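"""Natural-isotope-abundance correction of MS labeling data.

A TBDMS-derivatized glutamate ion drags two silicon atoms and a large
derivatization envelope into the mass spectrum; the measured mass envelope
of even an unlabeled standard therefore spreads over several mass units.
The correction matrix deconvolves that envelope and recovers the
biological 13C distribution of the 5-carbon backbone.
"""

import numpy as np

from emuflux.core import MDV
from emuflux.labeling import FragmentDB, correct_mdv, correction_matrix

db = FragmentDB.default()
frag = db.lookup("glu_m57")  # C19H40NO4Si2, 5 backbone carbons
M = correction_matrix(frag)

print(f"fragment {frag.name}: envelope from {frag.formula_no_backbone}")
print("what the instrument sees for a chemically unlabeled standard:")
raw = MDV(M[:, 0], normalize=False)
print("  raw:      ", np.round(raw.fractions, 4))
corrected, residual = correct_mdv(raw, frag)
print("  corrected:", np.round(corrected.fractions, 4), f"(NNLS residual {residual:.1e})")
print("after correction all signal returns to m0: the spread was purely")
print("natural Si/C/H/N/O heavy isotopes, not biological labeling")
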