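"""Gradient-echo sensitivity of the fast SMS vs resting-state protocols.

Evaluates the steady-state spoiled gradient-echo signal equation at
reference tissue values (T1 = 1.3 s, T2* = 40 ms) for the two protocols and
compares their sensitivities to T1 and T2* changes.
"""

import brainbeat as bb

sms = bb.gradient_echo_signal(m0=1.0, t1=1.3, t2star=0.040, tr=0.25, te=0.0116, flip_deg=48.0)
rest = bb.gradient_echo_signal(m0=1.0, t1=1.3, t2star=0.040, tr=2.0, te=0.0275, flip_deg=77.0)

print("protocol   TR      TE      FA    signal   |dS/dT1|   |dS/dT2*|")
print(f"SMS        0.25 s  11.6 ms 48°   {sms.signal:.4f}   {sms.sens_t1:.4f}     {sms.sens_t2star:.4f}")
print(f"resting    2.00 s  27.5 ms 77°   {rest.signal:.4f}   {rest.sens_t1:.4f}     {rest.sens_t2star:.4f}")
print()
print(f"SMS more T1-sensitive:   {sms.sens_t1 > rest.sens_t1}")
print(f"SMS less T2*-sensitive:  {sms.sens_t2star < rest.sens_t2star}")
print()
print("The short-TR SMS protocol is relatively T1-weighted: its larger cardiac")
print("modulation suggests the pulsatile signal is carried by blood-volume")
print("changes rather than susceptibility (T2*) changes.")
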