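"""Holographic Reduced Representation algebra on semantic pointers.

Binding via circular convolution produces a vector dissimilar to both
operands; unbinding with the involution recovers them approximately, and
exactly when the operand is unitary.  Structured scenes are sums of bound
pairs queried by unbinding.
"""

from nefopt import (
    SemanticPointer,
    circular_convolution,
    dot_similarity,
    make_unitary,
    unbind,
)
from nefopt.sp_algebra import random_unit

D = 64
square, blue, circle, red = (random_unit(s, D) for s in range(4))
scene = SemanticPointer(
    circular_convolution(square, blue).v + circular_convolution(circle, red).v
)
probe = unbind(scene, square)
print("scene = SQUARE (*) BLUE + CIRCLE (*) RED; probe = scene (*) SQUARE^-1")
print(f"  similarity(probe, BLUE): {dot_similarity(probe, blue):+.3f}  <- retrieved")
print(f"  similarity(probe, RED) : {dot_similarity(probe, red):+.3f}")

w = make_unitary(7, D)
v = random_unit(9, D)
bound = circular_convolution(v, w)
print("\nunitary operand:")
print(f"  |v|={v.norm():.6f}  |v (*) w|={bound.norm():.6f}  (norm preserved)")
print(f"  reconstruction error after unbinding: "
      f"{max(abs(unbind(bound, w).v - v.v)):.2e}")
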