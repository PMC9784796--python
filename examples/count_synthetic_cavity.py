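"""Generate one synthetic stained cavity image and count its cells.

The generator records every cell it draws, so the automatic count can be
scored against an exact truth.
"""

from milkscc import count_pipeline, generate_cavity

scene = generate_cavity(n_cells=150, dims=(480, 640), seed=11)
result = count_pipeline(scene.image)

print(f"ground truth : {scene.true_count} cells")
print(f"pipeline     : {result.count} connected domains counted")
err = abs(result.count - scene.true_count) / scene.true_count
print(f"rel. error   : {100 * err:.2f}%")
# One closed cell contour forms one connected domain, so the count of
# surviving domains is the somatic cell count of the image.
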