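"""Run the whole pipeline from one config and render the figure set.

Every stage (ingest -> profile -> embed -> cluster -> regional) writes
delimited-text artifacts plus a JSON-lines manifest; figures are rendered
from the completed run.
"""

import tempfile
from pathlib import Path

import rxscape as rx

with tempfile.TemporaryDirectory() as tmp:
    config = rx.PipelineConfig(
        out_dir=Path(tmp) / "run",
        simulation=rx.default_config(n_providers=300, n_drugs=40, n_classes=8,
                                     n_specialties=3, n_regions=3, seed=8),
        embedding_config=rx.EmbeddingConfig(pca_dims=20, perplexity=20,
                                            max_iters=400, n_restarts=2, seed=9),
        n_clusters=8,
        n_perm=25,
        seed=10,
    )
    manifest = rx.run_pipeline(config)
    for record in manifest:
        print(f"{record['stage']:>9}: {record['status']:>8}  "
              f"({len(record['outputs'])} artifact(s))")
    figures = rx.render_figures(config)
    print("Figures:", ", ".join(p.name for p in figures))
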