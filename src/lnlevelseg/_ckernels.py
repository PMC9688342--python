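"""Compiled convolution microkernels.

The stride-1 "same" convolutions dominate training time, so this module
compiles a ~100-line C file (embedded below) with the host C compiler at
import time and binds it via ctypes.  The kernels keep a 4-wide spatial tile
of 16-float vector accumulators in registers, which is an order of magnitude
faster than an im2col GEMM at the small channel counts these networks use.

If no C compiler is available (or compilation fails) the package falls back
to the pure-numpy im2col path in :mod:`lnlevelseg.nn`; results are identical
to float32 round-off.

Layout contract (see ``nn.Conv``): inputs are channels-last with a
pre-applied zero halo; filters are ``(k_total, C, 16)`` with the output
channel axis zero-padded to 16; outputs are written 16 channels wide.
"""

from __future__ import annotations

import ctypes
import hashlib
import os
import shutil
import subprocess
import tempfile

_SRC = r"""
#include <stddef.h>
typedef float v16 __attribute__((vector_size(64), aligned(4)));

/* y[..., x*ystr + yoff + f] = sum over taps/channels of xp * W.
   xp: channels-last with halo, row index (x+dx)*xstr + c;
   W: (ktot, C, 16) zero-padded output channels. */
void conv_fwd16(const float * restrict xp, const float * restrict W,
                float * restrict y,
                long N, long D, long H, long Wd, long C,
                long xstr, long ystr, long yoff,
                long Dp, long Hp, long Wp, long kd, long kh, long kw)
{
    long sxn = Dp*Hp*Wp*xstr, sxd = Hp*Wp*xstr, sxh = Wp*xstr;
    long syn = D*H*Wd*ystr, syd = H*Wd*ystr, syh = Wd*ystr;
    long ktot = kd*kh*kw;
    for (long n = 0; n < N; n++)
      for (long z = 0; z < D; z++)
        for (long r = 0; r < H; r++) {
          const float *xbase = xp + n*sxn + z*sxd + r*sxh;
          float *yrow = y + n*syn + z*syd + r*syh + yoff;
          long x0 = 0;
          for (; x0 + 4 <= Wd; x0 += 4) {
            v16 a0 = {0}, a1 = {0}, a2 = {0}, a3 = {0};
            for (long t = 0; t < ktot; t++) {
              long dz = t/(kh*kw), dy = (t/kw)%kh, dx = t%kw;
              const float *xrow = xbase + dz*sxd + dy*sxh + (x0+dx)*xstr;
              const float *wk = W + t*C*16;
              for (long c = 0; c < C; c++) {
                v16 w = *(const v16 *)(wk + c*16);
                a0 += xrow[c]          * w;
                a1 += xrow[xstr + c]   * w;
                a2 += xrow[2*xstr + c] * w;
                a3 += xrow[3*xstr + c] * w;
              }
            }
            *(v16 *)(yrow + x0*ystr)     = a0;
            *(v16 *)(yrow + (x0+1)*ystr) = a1;
            *(v16 *)(yrow + (x0+2)*ystr) = a2;
            *(v16 *)(yrow + (x0+3)*ystr) = a3;
          }
          for (; x0 < Wd; x0++) {
            v16 a = {0};
            for (long t = 0; t < ktot; t++) {
              long dz = t/(kh*kw), dy = (t/kw)%kh, dx = t%kw;
              const float *xv = xbase + dz*sxd + dy*sxh + (x0+dx)*xstr;
              const float *wk = W + t*C*16;
              for (long c = 0; c < C; c++)
                a += xv[c] * *(const v16 *)(wk + c*16);
            }
            *(v16 *)(yrow + x0*ystr) = a;
          }
        }
}

/* gW[t, c, 0:16] += sum over positions of xp[..., c] * gy[..., 0:16].
   gy: channels-last, 16-wide rows (zero-padded beyond the real F). */
void conv_gw16(const float * restrict xp, const float * restrict gy,
               float * restrict gW,
               long N, long D, long H, long Wd, long C, long xstr,
               long Dp, long Hp, long Wp, long kd, long kh, long kw)
{
    long sxn = Dp*Hp*Wp*xstr, sxd = Hp*Wp*xstr, sxh = Wp*xstr;
    long syn = D*H*Wd*16, syd = H*Wd*16, syh = Wd*16;
    long ktot = kd*kh*kw;
    for (long t = 0; t < ktot; t++) {
      long dz = t/(kh*kw), dy = (t/kw)%kh, dx = t%kw;
      float *gwk = gW + t*C*16;
      long c0 = 0;
      for (; c0 + 4 <= C; c0 += 4) {
        /* two accumulator sets per channel: enough independent FMA chains
           to cover the FMA latency on one core */
        v16 a0 = {0}, a1 = {0}, a2 = {0}, a3 = {0};
        v16 b0 = {0}, b1 = {0}, b2 = {0}, b3 = {0};
        for (long n = 0; n < N; n++)
          for (long z = 0; z < D; z++)
            for (long r = 0; r < H; r++) {
              const float *xrow = xp + n*sxn + (z+dz)*sxd + (r+dy)*sxh + dx*xstr + c0;
              const float *grow = gy + n*syn + z*syd + r*syh;
              long x = 0;
              for (; x + 2 <= Wd; x += 2) {
                v16 g0 = *(const v16 *)(grow + x*16);
                v16 g1 = *(const v16 *)(grow + (x+1)*16);
                const float *xv0 = xrow + x*xstr;
                const float *xv1 = xv0 + xstr;
                a0 += xv0[0] * g0;  b0 += xv1[0] * g1;
                a1 += xv0[1] * g0;  b1 += xv1[1] * g1;
                a2 += xv0[2] * g0;  b2 += xv1[2] * g1;
                a3 += xv0[3] * g0;  b3 += xv1[3] * g1;
              }
              for (; x < Wd; x++) {
                v16 g = *(const v16 *)(grow + x*16);
                const float *xv = xrow + x*xstr;
                a0 += xv[0] * g;
                a1 += xv[1] * g;
                a2 += xv[2] * g;
                a3 += xv[3] * g;
              }
            }
        *(v16 *)(gwk + c0*16)     += a0 + b0;
        *(v16 *)(gwk + (c0+1)*16) += a1 + b1;
        *(v16 *)(gwk + (c0+2)*16) += a2 + b2;
        *(v16 *)(gwk + (c0+3)*16) += a3 + b3;
      }
      for (; c0 < C; c0++) {
        v16 a = {0};
        for (long n = 0; n < N; n++)
          for (long z = 0; z < D; z++)
            for (long r = 0; r < H; r++) {
              const float *xrow = xp + n*sxn + (z+dz)*sxd + (r+dy)*sxh + dx*xstr + c0;
              const float *grow = gy + n*syn + z*syd + r*syh;
              for (long x = 0; x < Wd; x++)
                a += xrow[x*xstr] * *(const v16 *)(grow + x*16);
            }
        *(v16 *)(gwk + c0*16) += a;
      }
    }
}
"""

_lib = None


def _compile() -> ctypes.CDLL | None:
    cc = shutil.which("cc") or shutil.which("gcc")
    if cc is None:
        return None
    tag = hashlib.sha1(_SRC.encode()).hexdigest()[:16]
    cache = os.path.join(tempfile.gettempdir(), f"lnlevelseg_conv_{tag}.so")
    if not os.path.exists(cache):
        with tempfile.TemporaryDirectory() as td:
            src = os.path.join(td, "conv.c")
            out = os.path.join(td, "conv.so")
            with open(src, "w") as fh:
                fh.write(_SRC)
            try:
                subprocess.run(
                    [cc, "-O3", "-march=native", "-shared", "-fPIC", src, "-o", out],
                    check=True, capture_output=True)
            except (subprocess.CalledProcessError, OSError):
                return None
            shutil.move(out, cache)
    try:
        return ctypes.CDLL(cache)
    except OSError:
        return None


def get_lib() -> ctypes.CDLL | None:
    """The compiled kernel library, or None if unavailable."""
    global _lib
    if _lib is None:
        _lib = _compile() or False
    return _lib or None


_FP = ctypes.POINTER(ctypes.c_float)


def _a(x):
    return x.ctypes.data_as(_FP)


def conv_fwd16(lib, xp, w16, y, dims, xstr, ystr, yoff, kshape):
    n, d, h, wd, c = dims
    dp, hp, wp = xp.shape[1:4] if xp.ndim == 5 else (1,) + xp.shape[1:3]
    args = [_a(xp), _a(w16), _a(y)] + [
        ctypes.c_long(v) for v in
        (n, d, h, wd, c, xstr, ystr, yoff, dp, hp, wp, *kshape)]
    lib.conv_fwd16(*args)


def conv_gw16(lib, xp, gy16, gw16, dims, xstr, kshape):
    n, d, h, wd, c = dims
    dp, hp, wp = xp.shape[1:4] if xp.ndim == 5 else (1,) + xp.shape[1:3]
    args = [_a(xp), _a(gy16), _a(gw16)] + [
        ctypes.c_long(v) for v in (n, d, h, wd, c, xstr, dp, hp, wp, *kshape)]
    lib.conv_gw16(*args)
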