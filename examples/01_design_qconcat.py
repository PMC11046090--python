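"""Design QconCAT internal-standard constructs for a toy proteome.

Selects one proteotypic peptide per target protein (fully tryptic, unique
across the proteome, 7-20 residues, standard exclusion motifs) and links
the peptides into artificial concatamer proteins whose LysC + trypsin
digestion releases every peptide exactly once.
"""

from pathlib import Path

import mrmquant as mq
from mrmquant.io import read_fasta

proteome = read_fasta(Path(__file__).parent / "data" / "toy_proteome.fasta")
report = mq.select_proteotypic(proteome, list(proteome))

print(f"targets: {len(proteome)}  peptides selected: {len(report.peptides)}  "
      f"failures: {len(report.failures)}")
for pid, peps in list(report.chosen.items())[:3]:
    print(f"  {pid}: {peps[0].sequence}")

constructs = mq.assemble_qconcat(report.peptides, capacity=50)
for c in constructs:
    v = mq.validate_qconcat(c)
    released = sum(1 for n in v.released.values() if n == 1)
    print(f"{c.construct_id}: {len(c.peptides)} peptides, length "
          f"{len(c.full_sequence)} aa, digestion releases {released}/{len(c.peptides)}")

# Every peptide released exactly once means each target protein gets one
# heavy-labeled internal standard when the spiked construct is digested.
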