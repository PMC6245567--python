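"""Generate a synthetic claims population and round-trip it through PUF tables.

Builds a small provider population with planted specialty/region structure,
applies the privacy-censoring rule (cells < 11 claims suppressed), writes the
three PUF-shaped tables, and reads them back.
"""

import tempfile
from pathlib import Path

import rxscape as rx

cfg = rx.default_config(n_providers=300, n_drugs=40, n_classes=8,
                        n_specialties=3, n_regions=2, seed=0)
matrix, annotations, class_map, truth = rx.generate_population(cfg)
print(f"Generated {matrix.n_providers} providers x {matrix.n_drugs} drugs, "
      f"censor threshold {matrix.censor_threshold}")

trimmed, report = rx.drop_empty(matrix)
print(f"After censoring, {report['providers_retained']} providers have at "
      f"least one surviving (>= {matrix.censor_threshold} claims) cell; "
      f"{report['providers_removed']} were removed entirely.")

with tempfile.TemporaryDirectory() as tmp:
    paths = rx.write_puf_tables(trimmed, annotations.loc[trimmed.providers], tmp)
    back, _ = rx.read_puf(paths["provider"], paths["drug"], paths["link"])
    print(f"Round-trip through {len(paths)} delimited tables lossless:",
          trimmed.equals(back))
# The censored matrix is what a public release would contain; `truth` keeps
# the uncensored counts and the planted specialty/region labels for checks.
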