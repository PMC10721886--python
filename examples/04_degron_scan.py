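"""Scan sequences for the DDR-responsive beta-TrCP variant degron
[D/E/S/T]-[D/E/S]-G-x-x-[S/T]-Q and annotate known phosphosites.

Runs on a tiny in-memory FASTA: one sequence carries the conserved degron
of the actin regulator Dbn1 (S-E-G-Y-F-S-Q), one carries the canonical
degron only, one carries neither.
"""

import pandas as pd

from ubiquant import join_phospho, scan_proteome, variant_degron
from ubiquant.io_tables import ProteinSequences

seqs = ProteinSequences(
    {
        "DBN1LIKE": ("degron-bearing", "MAKLNPRVWHCSEGYFSQSQDEDAKLW"),
        "CANONICAL": ("canonical only", "MAKDSGIESAKLWNPRV"),
        "NEITHER": ("no degron", "MAKLNPRVWHAKLW"),
    }
)

matches = scan_proteome(seqs, variant_degron())
print(matches)
print(f"{matches.attrs['n_proteins_matched']} of {len(seqs)} proteins carry the variant degron")

phospho = pd.DataFrame({"accession": ["DBN1LIKE"], "position": [17], "kinase": ["ATM"]})
annotated = join_phospho(matches, phospho)
print(annotated[["accession", "start", "end", "stq_position", "known_phospho", "kinase"]])
# stq_position is the phosphoacceptor serine/threonine directly preceding
# the motif's glutamine: phosphorylation there (by ATM/ATR) primes the
# degron for beta-TrCP recognition.
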