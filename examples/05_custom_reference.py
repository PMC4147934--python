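"""Load an editable reference subtype matrix from TSV.

Reference profiles are configuration, not code: a 4 x 15 table of values
in [-1, 1] (rows = subtypes, columns = gene sets).  The shipped
``data/reference_subtypes_synthetic.tsv`` is a synthetic placeholder
illustrating the format - edit its values and column names to match
your own gene-set panel before real use.
"""

from pathlib import Path

import prosig as ps

path = Path(__file__).parent / "data" / "reference_subtypes_synthetic.tsv"
refs = ps.read_reference_matrix(
    path,
    prognosis={"BP-E/P/Pr": "bad", "BP-ERG": "bad", "GP1": "good", "GP2": "good"},
)
print(f"loaded {len(refs.subtype_names)} subtypes x {len(refs.geneset_names)} gene sets")
print("bad-prognosis subtypes: ", refs.bad_subtypes())
print("good-prognosis subtypes:", refs.good_subtypes())
print("\ninter-subtype correlations (r_kh, used by the dependent-correlations test):")
print(refs.data.T.corr().round(2).to_string())
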