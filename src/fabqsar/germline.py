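"""Packaged immunoglobulin constant-domain alleles and IMGT delimitations.

The workflow targets IgG1-Kappa Fab fragments: the heavy chain is a
variable domain (VH) followed by the IGHG1*01 CH1 domain, the light chain
a VL (kappa) domain followed by the IGLK1*01 constant domain. Because all
samples share the same constant alleles, constant-domain sequence
descriptors are static; constant-domain *structural* descriptors are not.
"""

from __future__ import annotations

#: IMGT variable-domain region delimitations (IMGT unique numbering,
#: positions are 1-based inclusive).
V_REGION_BOUNDS = {
    "FR1": (1, 26),
    "CDR1": (27, 38),
    "FR2": (39, 55),
    "CDR2": (56, 65),
    "FR3": (66, 104),
    "CDR3": (105, 117),
    "FR4": (118, 128),
}

#: Conserved anchor positions of the IMGT unique numbering.
ANCHOR_POSITIONS = {"Cys23": 23, "Trp41": 41, "Cys104": 104, "PheTrp118": 118}

#: IGHG1*01 CH1 domain (98 residues).
IGHG1_CH1 = (
    "ASTKGPSVFPLAPSSKSTSGGTAALGCLVKDYFPEPVTVSWNSGALTSGVHTFPAVLQSS"
    "GLYSLSSVVTVPSSSLGTQTYICNVNHKPSNTKVDKKV"
)

#: Kappa light-chain constant domain, allele named IGLK1*01 here (107
#: residues).
IGLK1_CL = (
    "RTVAAPSVFIFPPSDEQLKSGTASVVCLLNNFYPREAKVQWKVDNALQSGNSQESVTEQD"
    "SKDSTYSLSSTLTLSKADYEKHKVYACEVTHQGLSSPVTKSFNRGEC"
)

#: Approximate beta-strand (A–G) delimitations on the packaged constant
#: domains, 0-based half-open on the domain sequence. Derived from the
#: IMGT C-domain strand layout; loops between strands are not annotated.
C_STRAND_BOUNDS = {
    "CH1": {
        "A": (0, 13), "B": (15, 27), "C": (30, 38), "D": (41, 49),
        "E": (52, 63), "F": (66, 78), "G": (82, 94),
    },
    "CL": {
        "A": (0, 13), "B": (15, 27), "C": (30, 38), "D": (41, 49),
        "E": (52, 63), "F": (66, 78), "G": (82, 95),
    },
}

#: Germline-like framework templates used by the synthetic fixture
#: generator. Each satisfies the conserved anchors (Cys23, Trp41, Cys104,
#: Phe/Trp118) under the package's anchor-scan numbering; FR3 carries the
#: full 39 IMGT positions (66–104).
HEAVY_FRAMEWORKS = {
    "FR1": "EVQLVESGGGLVQPGGSLRLSCAAS",           # 25 res, Cys at index 21
    "FR2": "IHWVRQAPGKGLEWVSG",                   # 17 res, Trp at index 2
    "FR3": "NYYADSVKGRFTISRDNSKNTLYLQMNSLRAEDTAVYYC",  # 39 res, ends Cys104
    "FR4": "WGQGTLVTVSS",                         # 11 res, Trp118 first
}

KAPPA_FRAMEWORKS = {
    "FR1": "DIQMTQSPSSLSASVGDRVTITCRAS",          # 26 res, Cys at index 22
    "FR2": "LNWYQQKPGKAPKLLIY",                   # 17 res, Trp at index 2
    "FR3": "GASNRATGVPSRFSGSGSGTDFTLTISSLQPEDFATYYC",  # 39 res, ends Cys104
    "FR4": "FGQGTKVEIKR",                         # 11 res, Phe118 first
}
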