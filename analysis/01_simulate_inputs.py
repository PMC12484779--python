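#!/usr/bin/env python
"""Simulate every input the downstream analyses consume.

Emulates the study's three data streams with planted ground truth:

* a cluster-structured embedding lexicon plus per-subject stories under
  two writing conditions — the "imagery" condition samples tokens from
  all semantic clusters (divergent writing, so adjacent text windows
  differ in cluster composition), the "semantic" condition stays within
  one cluster;
* multi-subject, multi-trial region-by-time BOLD matrices with planted
  node-block covariance (condition-specific blocks);
* a behavioral table with a known imagery -> semantic feature ->
  writing-score mediation structure.

Raw data land under scratch/sim/ (regenerated on demand); a small
manifest of what was simulated is written to results/simulation_summary.tsv.
"""

from pathlib import Path

import pandas as pd

from creanet import io, synthetic as syn

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "sim"
RESULTS = ROOT / "results"

SEED = 20251001
N_SUBJECTS = 40


def story_length(subject: int) -> int:
    """Story lengths vary across subjects (45-75 tokens) so the word-count
    control downstream has real length differences to remove."""
    return 45 + 10 * (subject % 4)

LEXICON_SPEC = syn.LexiconSpec(
    n_clusters=6, words_per_cluster=30, dim=50, within_noise_sd=0.15, seed=SEED
)
BOLD_SPEC = syn.BoldSpec(
    n_nodes=60,
    n_networks=6,
    n_blocks=4,
    T_trial=30,
    n_trials=10,
    n_subjects=8,
    noise_sd=0.1,
    seed=SEED + 1,
)
MEDIATION_SPEC = syn.MediationSpec(
    n=N_SUBJECTS * 2, a_path=0.5, b_path=0.4, c_prime=0.2, noise_sd=1.0, seed=SEED + 2
)


def main() -> None:
    SCRATCH.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(parents=True, exist_ok=True)

    lexicon = syn.make_lexicon(LEXICON_SPEC)
    io.write_lexicon(lexicon, SCRATCH / "lexicon.w2v.txt")

    stories = []
    for s in range(N_SUBJECTS):
        stories.append(
            syn.make_story(
                lexicon,
                story_length(s),
                [1.0 / 6.0] * 6,
                seed=SEED + 100 + s,
                source_id=f"sub{s + 1:02d}",
                condition="imagery",
            )
        )
        stories.append(
            syn.make_story(
                lexicon,
                story_length(s),
                [1.0 if c == s % 6 else 0.0 for c in range(6)],
                seed=SEED + 200 + s,
                source_id=f"sub{s + 1:02d}",
                condition="semantic",
            )
        )
    io.write_stories(stories, SCRATCH / "stories.tsv")

    series = syn.make_bold(BOLD_SPEC)
    io.write_bold_set(series, SCRATCH / "bold")

    behavior = syn.make_mediation_table(MEDIATION_SPEC)
    behavior.insert(0, "subject", [f"p{i + 1:03d}" for i in range(len(behavior))])
    behavior.to_csv(SCRATCH / "behavior.tsv", sep="\t", index=False)

    summary = pd.DataFrame(
        [
            {"input": "lexicon", "detail": f"{len(lexicon)} words, dim {lexicon.dim}"},
            {"input": "stories", "detail": f"{len(stories)} stories, 45-75 tokens, 2 conditions"},
            {"input": "bold", "detail": f"{BOLD_SPEC.n_subjects} subjects x 2 conditions x {BOLD_SPEC.n_trials} trials, {BOLD_SPEC.n_nodes} nodes"},
            {"input": "behavior", "detail": f"{len(behavior)} rows, planted indirect effect {MEDIATION_SPEC.a_path * MEDIATION_SPEC.b_path:.2f}"},
        ]
    )
    summary.to_csv(RESULTS / "simulation_summary.tsv", sep="\t", index=False)
    print(summary.to_string(index=False))
    print(f"\nraw inputs written under {SCRATCH}")


if __name__ == "__main__":
    main()
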