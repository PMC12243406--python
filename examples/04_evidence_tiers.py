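"""Classify drug-target candidates into evidence tiers.

Feeds the classifier the canonical evidence profiles: protein MR plus
consistent transcript SMR plus colocalisation (tier 1), MR plus
colocalisation only (tier 2), MR only (tier 3), and a transcript effect
opposite in direction to the protein effect (excluded).
"""

import math

from targetmr import ColocResult, EvidenceRow, MRResult, SMRResult, classify_tier


def mr(beta, p_fdr):
    return MRResult("gene", "ivw", 2, beta, 0.05, 1e-5, math.exp(beta),
                    math.exp(beta - 0.1), math.exp(beta + 0.1), p_fdr=p_fdr)


def smr(b, p, p_heidi=0.5):
    return SMRResult("gene", "snp", b, 0.2, p, math.exp(b), 0.5, 2.0, p_heidi, 10, "pass")


def coloc(pp4):
    r = (1 - pp4) / 4
    return ColocResult("gene", r, r, r, r, pp4, 200, (1e-4, 1e-4, 1e-5))


profiles = {
    "protective, full evidence":      EvidenceRow("g", "1", mr(-0.15, 0.001), smr(-0.6, 0.001), coloc(0.940)),
    "protective, MR + coloc":         EvidenceRow("g", "1", mr(-0.55, 0.042), smr(-0.2, 0.30), coloc(0.706)),
    "risk, MR only":                  EvidenceRow("g", "3A", mr(0.29, 0.033), smr(0.1, 0.40), coloc(0.447)),
    "protective, no expression data": EvidenceRow("g", "3B", mr(-0.60, 0.033), None, coloc(0.001)),
    "opposite transcript direction":  EvidenceRow("g", "2", mr(-0.15, 0.001), smr(0.6, 0.001), coloc(0.94)),
}
for label, row in profiles.items():
    call = classify_tier(row)
    reasons = f"  [{'; '.join(call.reasons)}]" if call.reasons else ""
    print(f"{label:34s} -> tier {call.tier}{reasons}")
# Tier 1 = MR + both supporting lines; tier 2 = one line; tier 3 = MR alone;
# a significant transcript effect opposite to the protein effect excludes
# the target because the dual directions make it undruggable evidence.
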