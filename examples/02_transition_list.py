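"""Build a scheduled MRM transition list with instrument parameters.

For one peptide: pick the three highest y-ions, compute Q1/Q3 for the
light (endogenous) and heavy (internal standard) forms, and fill in the
triple-quadrupole voltages from their linear ramps
(DP = 0.049 Q1 + 42.6, CE = 0.036 Q1 + 6.9 for 2+, CXP = 0.0391 Q3 - 2.23,
EP = 10). Also shows the acylcarnitine precursor-ion-scan settings.
"""

import mrmquant as mq
from mrmquant.assay import schedule, transitions_to_frame

peptide = mq.Peptide("LVNELTEFAK", parent_protein="ALBU")
transitions = mq.build_transitions(peptide, predicted_rt=21.4)
scheduled, report = schedule(transitions)

df = transitions_to_frame(scheduled)
print(df[["peptide", "label", "q1", "fragment", "q3", "dp", "ce", "cxp", "rt",
          "window_start", "window_end"]].round(4).to_string(index=False))
print(f"max concurrent transitions: {report.max_concurrent}, "
      f"dwell {report.min_dwell_ms:.0f} ms per transition in a 1-s cycle")
# Heavy Q1 sits label-shift/charge above light Q1; each transition is only
# monitored inside its 2-min window around the predicted retention time.

for species in ("C4", "C12:1", "C16"):
    product, ce = mq.acylcarnitine_ce(species)
    print(f"acylcarnitine {species}: precursor-ion scan for m/z {product}, CE {ce:.0f} V")
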