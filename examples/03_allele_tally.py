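"""Tally nonsynonymous/synonymous substitutions across an allele set.

Builds a small reference gene (signal-peptide coding region + mature-protein
coding region) and a handful of alleles, collapses duplicate cDNAs, pools
distinct substitutions, and reports the nonsyn/syn count ratio separately
for the SPCR and the MPCR.  A higher MPCR ratio is the allele-level
signature of positive selection on the mature protein.
"""

from tandemfam import tally_alleles
from tandemfam.gene_models import GeneModel, Region

#           SPCR (3 codons)   MPCR (7 codons incl. stop)
parent = "ATGAAACCC" + "GGGTTTACCGATTGGCATTAA"
model = GeneModel("gene1", "chr",
                  [Region("spcr", 0, 9), Region("mpcr", 9, 30)])

ref = parent
alleles = {
    "pop1_a": ref,                                  # identical to reference
    "pop1_b": ref[:11] + "A" + ref[12:],            # synonymous GGG->GGA
    "pop2_a": ref[:11] + "A" + ref[12:],            # same substitution again
    "pop2_b": (ref[:11] + "A" + ref[12:])[:12] + "G"
              + (ref[:11] + "A" + ref[12:])[13:],   # + nonsyn TTT->GTT
    "pop3_a": ref[:4] + "C" + ref[5:],              # nonsyn AAA->ACA in SPCR
}
tally = tally_alleles(model, parent, alleles)

print(f"gene: {tally.gene_id}")
print(f"total cDNAs {tally.n_total}, unique cDNAs {tally.n_unique_cdna}, "
      f"unique proteins {tally.n_unique_protein}")
for region in ("spcr", "mpcr"):
    r = tally.regions[region]
    shown = "N/A" if r["ratio"] is None else f"{r['ratio']:.2f}"
    print(f"{region.upper()}: nonsyn/syn = {shown} "
          f"({r['nonsyn']}/{r['syn']})")
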