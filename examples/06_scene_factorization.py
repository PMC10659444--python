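"""Disentangling object identity and position from a sparse-feature scene.

A synthetic sparse feature map (standing in for a convolutional sparse
code) is rolled into one scene vector; a resonator factorizes it into
object identity and 2-D translation.  The residue factor structure
stores 40 codebook vectors where the standard structure stores 220, and
brute-force search would evaluate 110,250 candidates.
"""

from residuehd import (
    SceneCodec,
    brute_force_search_size,
    codebook_vector_count,
    encode_scene,
    encode_templates,
    factorize_scene,
    generate_synthetic_scene,
)

codec = SceneCodec.make(n_features=8, D=2000, moduli=(3, 5, 7), seed=0)
templates, scene, truth = generate_synthetic_scene(
    10, grid=(105, 105), n_features=8, seed=1
)
encoded = encode_templates(templates, codec)
s = encode_scene(scene, codec)
print(f"truth: object {truth[0]} at ({truth[1]}, {truth[2]}) on a 105x105 grid")
print(f"search space: {brute_force_search_size(10, 105)} candidate scenes\n")

for mode in ("residue", "standard"):
    i, x, y, evals, ok = factorize_scene(s, encoded, codec, mode=mode, seed=2)
    stored = codebook_vector_count(10, 105, (3, 5, 7), mode)
    print(f"{mode:8s}: decoded object {i} at ({x}, {y}) "
          f"[{'correct' if (i, x, y) == truth else 'WRONG'}] -- "
          f"{stored} stored vectors, {evals} codebook evaluations")
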