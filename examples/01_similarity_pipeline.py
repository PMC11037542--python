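"""Build every similarity layer from a toy association list and disease DAG.

Constructs a six-disease MeSH-style hierarchy and a small association
matrix, then prints the semantic (DSS), functional (MFS), kernel (GIP) and
integrated (IM/ID) similarities for a few pairs.
"""

import numpy as np

from hypermir.io import AssociationMatrix, read_dag_table
from hypermir.similarity import build_integrated_similarities, \
    disease_semantic_similarity
import tempfile, os

DAG_ROWS = [
    ("neoplasms", "C04"),
    ("breast-neoplasms", "C04.100"),
    ("lung-neoplasms", "C04.200"),
    ("carcinoma-nsclc", "C04.200.100"),
    ("cvd", "C14"),
    ("heart-failure", "C14.100"),
]

ASSOC = np.array([
    # bre lun nsclc hf  (columns: 4 diseases with known associations)
    [1, 1, 0, 0],   # mir-21 : both tumours
    [1, 0, 1, 0],   # mir-155
    [0, 1, 1, 0],   # mir-17
    [0, 0, 0, 1],   # mir-1 : cardiac
    [1, 1, 1, 0],   # mir-125b
], dtype=np.int8)

with tempfile.TemporaryDirectory() as tmp:
    dag_path = os.path.join(tmp, "dag.tsv")
    with open(dag_path, "w") as fh:
        for d, code in DAG_ROWS:
            fh.write(f"{d}\t{code}\n")
    dag = read_dag_table(dag_path)

T = AssociationMatrix(
    ["mir-21", "mir-155", "mir-17", "mir-1", "mir-125b"],
    ["breast-neoplasms", "lung-neoplasms", "carcinoma-nsclc",
     "heart-failure"], ASSOC)

dss = disease_semantic_similarity(dag, delta=0.5)
i, j = dag.disease_ids.index("breast-neoplasms"), \
    dag.disease_ids.index("lung-neoplasms")
print(f"DSS(breast, lung)          = {dss.S[i, j]:.4f}  "
      "(siblings under 'neoplasms': moderate semantic overlap)")
k = dag.disease_ids.index("heart-failure")
print(f"DSS(breast, heart-failure) = {dss.S[i, k]:.4f}  "
      "(disjoint trees: no shared ancestry)")

sims = build_integrated_similarities(T, dag=dag)
m = T.mirna_ids.index
print(f"MFS(mir-21, mir-125b)      = {sims['MFS'].S[m('mir-21'), m('mir-125b')]:.4f}  "
      "(largely overlapping disease sets)")
print(f"MFS(mir-21, mir-1)         = {sims['MFS'].S[m('mir-21'), m('mir-1')]:.4f}  "
      "(tumour vs cardiac miRNA)")
print(f"GPSM(mir-21, mir-125b)     = {sims['GPSM'].S[m('mir-21'), m('mir-125b')]:.4f}  "
      "(Gaussian kernel on association profiles)")
print(f"IM(mir-21, mir-125b)       = {sims['IM'].S[m('mir-21'), m('mir-125b')]:.4f}  "
      "(average of MFS and GIP where both defined)")
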