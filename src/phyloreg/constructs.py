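"""Luciferase reporter construct inserts bundled as a sequence fixture.

Three LTR7 promoter variants cloned for reporter assays: the LTR7down
consensus, the LTR7up consensus, and the LTR7up consensus carrying the
8-bp deletion that removes the SOX2/3 binding motif unique to the 7up
lineage.  Restriction-site overhangs are included as ordered.
"""

CONSTRUCTS = {
    "7down": (
        "GCTAGCTGTCAGGCCTCTGAGCCCAAGCTAAGCCATCATATCCCCTGTGACCTGCACGTACACATCCA"
        "GATGGCCGGTTCCTGCCTTAACTGATGACATTCCACCACAAAAGAAGTGAAAATGGCCTGTTCCTGCC"
        "TTAACTGATGACATTATCTTGTGAAATTCCTTCTCCTGGCTCATCCTGGCTCAAAAGCTCCCCTACTG"
        "AGCACCTTGTGACCCCCACTCCTGCCCGCCAGAGAACAACCCCCCTTTGACTGTAATTTTCCTTTACC"
        "TACCCAAATCCTATAAAACGGCCCCACCCCTATCTCCCTTCGCTGACTCTCTTTTCGGACTCAGCCCG"
        "CCTGCACCCAGGTGAAATAAACAGCTTTATTGCTCACACAAAGCCTGTTTGGTGGTCTCTTCACACGG"
        "ACGCGCATGCTCGAG"
    ),
    "LTR7upcons": (
        "GCTAGCTGTCAGGCCTCTGAGCCCAAGCCAAGCCATCGCATCCCCTGTGACTTGCACGTATACGCCCA"
        "GATGGCCTGAAGTAACTGAAGAATCACAAAAGAAGTGAATATGCCCTGCCCCACCTTAACTGATGACA"
        "TTCCACCACAAAAGAAGTGTAAATGGCCGGTCCTTGCCTTAAGTGATGACATTACCTTGTGAAAGTCC"
        "TTTTCCTGGCTCATCCTGGCTCAAAAAGCACCCCCACTGAGCACCTTGCGACCCCCACTCCTGCCCGC"
        "CAGAGAACAAACCCCCTTTGACTGTAATTTTCCTTTACCTACCCAAATCCTATAAAACGGCCCCACCC"
        "TTATCTCCCTTCGCTGACTCTCTTTTCGGACTCAGCCCGCCTGCACCCAGGTGAAATAAACAGCCATG"
        "TTGCTCACACAAAGCCTGTTTGGTGGTCTCTTCACACGGACGCGCATGCTCGAG"
    ),
    "LTR7upcons_AAAGAAG_deletion": (
        "GCTAGCTGTCAGGCCTCTGAGCCCAAGCCAAGCCATCGCATCCCCTGTGACTTGCACGTATACGCCCA"
        "GATGGCCTGAAGTAACTGAAGAATCACAAAAGAAGTGAATATGCCCTGCCCCACCTTAACTGATGACA"
        "TTCCACCATTGTAAATGGCCGGTCCTTGCCTTAAGTGATGACATTACCTTGTGAAAGTCCTTTTCCTG"
        "GCTCATCCTGGCTCAAAAAGCACCCCCACTGAGCACCTTGCGACCCCCACTCCTGCCCGCCAGAGAAC"
        "AAACCCCCTTTGACTGTAATTTTCCTTTACCTACCCAAATCCTATAAAACGGCCCCACCCTTATCTCC"
        "CTTCGCTGACTCTCTTTTCGGACTCAGCCCGCCTGCACCCAGGTGAAATAAACAGCCATGTTGCTCAC"
        "ACAAAGCCTGTTTGGTGGTCTCTTCACACGGACGCGCATGCTCGAG"
    ),
}


def fixture_constructs() -> dict[str, str]:
    """Return the three reporter construct sequences by name."""
    return dict(CONSTRUCTS)
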