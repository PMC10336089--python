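"""Demo: t-SNE clustering of persistent Dirac features.

Featurizes a batch of structure files (e.g. trajectory frames exported as
XYZ) and embeds them with t-SNE.  Thin wiring around scikit-learn; not part
of the tested core.

Usage: python examples/cluster_tsne.py FRAME_DIR out.png
"""

import sys
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
from sklearn.manifold import TSNE

from pdirac import featurize_table, oihp_config, read_structure


def main(frame_dir: str, out_png: str) -> None:
    files = sorted(Path(frame_dir).glob("*.xyz"))
    mols = [read_structure(f) for f in files]
    table = featurize_table(mols, oihp_config())
    emb = TSNE(n_components=2, init="pca", random_state=0).fit_transform(
        table.drop(columns="name").to_numpy()
    )
    plt.scatter(emb[:, 0], emb[:, 1], s=8)
    plt.xlabel("t-SNE 1")
    plt.ylabel("t-SNE 2")
    plt.savefig(out_png, dpi=150)
    print(f"embedded {len(mols)} frames -> {out_png}")


if __name__ == "__main__":
    main(sys.argv[1], sys.argv[2])
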