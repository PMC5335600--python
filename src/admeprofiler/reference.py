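"""Vendored reference structures used in documentation and validation.

``STREPTOMYCIN_SMILES`` is the standard structure of the aminoglycoside
antibiotic streptomycin (C21H39N7O12, MW 581.58): streptidine bearing two
guanidine groups, streptose with its aldehyde, and N-methyl-L-glucosamine.
The guanidines are written in the ring-NH-C(=NH)-NH2 tautomer, the
convention under which the reference fragmental property values for this
structure were derived.
"""

STREPTOMYCIN_SMILES = (
    "CNC1C(O)C(O)C(CO)OC1OC1C(C=O)(O)C(C)OC1OC1C(O)C(O)C(NC(=N)N)C(O)C1NC(=N)N"
)
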