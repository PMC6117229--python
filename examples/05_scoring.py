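"""Additive candidate scoring with scaled metadata terms.

Three triazine candidates for one formula: the fragmenter and spectral
scores come from external tools; data-source counts, list flags and assay
data come from the registry metadata. Each metadata category is scaled to
[0, 1] by its column maximum (missing = 0), and the combined score is the
sum — maximum 7 with two core terms and five categories at unit weights.
A candidate missing two metadata values ranks below one with a full row
even when the experimental evidence is comparable.
"""

from msready import inchikey
from msready.scoring import CandidateScore, ScoringConfig, rank, score_candidates

CATEGORIES = ("data_sources", "norman", "pubmed_refs", "stoffident", "toxcast")
config = ScoringConfig(metadata_categories=CATEGORIES, grouping=False)

candidates = [
    CandidateScore(
        "Terbutylazine", inchikey=inchikey("CCNc1nc(Cl)nc(NC(C)(C)C)n1"),
        fragmenter=1.0, spectral_similarity=1.0,
        metadata={"data_sources": 3880, "norman": 1, "pubmed_refs": 410,
                  "stoffident": 1, "toxcast": 31.0},
    ),
    CandidateScore(
        "Propazine", inchikey=inchikey("CC(C)Nc1nc(Cl)nc(NC(C)C)n1"),
        fragmenter=0.92, spectral_similarity=0.5774,
        metadata={"data_sources": 1560, "norman": 1, "pubmed_refs": 880,
                  "stoffident": 1, "toxcast": 14.0},
    ),
    CandidateScore(
        "Sebutylazine", inchikey=inchikey("CCNc1nc(Cl)nc(NC(C)CC)n1"),
        fragmenter=0.97, spectral_similarity=0.90,
        metadata={"data_sources": 182, "norman": None, "pubmed_refs": 12,
                  "stoffident": 1, "toxcast": None},
    ),
]

score_candidates(candidates, config)
print(f"maximum achievable score: {config.max_score}")
for cand in rank(candidates):
    terms = ", ".join(f"{k}={v:.3f}" for k, v in cand.scaled.items())
    print(f"{cand.identifier:15s} combined {cand.combined:.3f}  ({terms})")
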