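"""Generate a two-class lung-phantom corpus and inspect its class signal.

The two classes share geometry, rib banding and noise for a given seed;
the diseased class only adds smooth opacity blobs inside the lung fields.
"""

from cyclecf import Label, PhantomParams, generate_phantom, make_corpus, write_corpus
from cyclecf.phantom import lung_mask_for_seed

params = PhantomParams(image_size=64, seed=0)
corpus = make_corpus(params, n_per_class=20)
root = write_corpus(corpus, "scratch/phantom_demo")
print(f"wrote {len(corpus)} PNGs under {root}/CLASS_X and {root}/CLASS_Y")

# the class difference is purely textural: compare a paired X/Y image
x = generate_phantom(params, Label.CLASS_X, seed=5)
y = generate_phantom(params, Label.CLASS_Y, seed=5)
mask = lung_mask_for_seed(params, seed=5)
print(f"mean intensity inside the lung fields:  normal {x.pixels[mask].mean():.3f}"
      f"  opacity {y.pixels[mask].mean():.3f}")
print(f"outside the lung fields the pair is identical: "
      f"{(x.pixels[~mask] == y.pixels[~mask]).all()}")
# The higher masked mean for the opacity class is the signal the classifier
# learns; everything else (geometry, ribs, noise) is shared nuisance.
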