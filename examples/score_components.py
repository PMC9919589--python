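"""Break a UIQM score into its colorfulness/sharpness/contrast components.

Scores a clean synthetic scene and two degraded counterparts, showing how
each working condition moves the components.
"""

from seepvision import PRESETS, degrade_underwater, make_scene, uiqm

scene = make_scene(seed=3, size=(64, 64))
for name in ("blue_cast", "noisy"):
    deg = degrade_underwater(scene, PRESETS[name])
    a, b = uiqm(scene), uiqm(deg)
    print(f"--- condition: {name}")
    print(f"  clean    uicm={a.uicm:7.3f} uism={a.uism:7.3f} "
          f"uiconm={a.uiconm:6.3f} total={a.total:6.3f}")
    print(f"  degraded uicm={b.uicm:7.3f} uism={b.uism:7.3f} "
          f"uiconm={b.uiconm:6.3f} total={b.total:6.3f}")
print()
print("The color cast collapses the opponent-channel statistics, pulling the")
print("colorfulness term UICM down sharply; the weighted total drops with it.")
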