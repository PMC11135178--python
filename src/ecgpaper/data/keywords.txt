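atrial fibrillation
sinus rhythm
sinus tachycardia
sinus bradycardia
ventricular tachycardia
premature ventricular complex
left bundle branch block
right bundle branch block
first degree AV block
myocardial infarction
ST elevation
ST depression
T wave inversion
prolonged QT
QT interval
QRS widening
left ventricular hypertrophy
right axis deviation
left axis deviation
atrial flutter
junctional rhythm
paced rhythm
ischemia
cardiomyopathy
pericarditis
hyperkalemia
digoxin effect
normal ECG
abnormal ECG
follow up
repeat ECG
compare with prior
lead misplacement
artifact
low voltage
poor R wave progression
biphasic T wave
U wave
PR depression
early repolarization
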