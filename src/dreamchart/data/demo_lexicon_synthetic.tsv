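abandoned	-2.0	0.6
afraid	-2.2	0.5
aggressive	-1.6	0.7
alarmed	-1.7	0.6
alone	-1.0	0.8
amazed	2.4	0.6
amazing	2.8	0.5
angry	-2.3	0.5
anguish	-2.9	0.6
anxious	-1.9	0.6
ashamed	-2.1	0.6
attacked	-2.4	0.7
awful	-2.9	0.5
bad	-2.5	0.5
beautiful	2.9	0.4
betrayed	-2.6	0.6
blessed	2.9	0.6
bliss	3.2	0.5
bored	-1.2	0.6
brave	2.2	0.5
bright	1.5	0.6
broken	-1.9	0.7
calm	1.3	0.5
care	1.8	0.6
chased	-1.5	0.8
cheerful	2.5	0.5
comfort	1.9	0.5
confident	2.1	0.5
confused	-1.1	0.6
content	1.7	0.5
cried	-2.0	0.7
crying	-2.1	0.6
danger	-2.4	0.6
dark	-1.1	0.8
dead	-3.1	0.6
death	-2.9	0.7
delight	2.8	0.5
delighted	2.9	0.5
depressed	-2.6	0.6
despair	-3.0	0.6
destroyed	-2.6	0.7
devastated	-3.1	0.6
died	-2.8	0.7
dread	-2.6	0.6
dying	-2.8	0.7
ecstatic	3.3	0.5
embarrassed	-1.8	0.6
empty	-1.3	0.7
enjoy	2.2	0.5
enjoyed	2.3	0.5
evil	-3.1	0.6
excited	2.4	0.5
excitement	2.4	0.6
fail	-2.2	0.6
failed	-2.3	0.6
falling	-1.0	0.9
fear	-2.5	0.5
feared	-2.4	0.6
fight	-1.6	0.7
fighting	-1.7	0.7
fled	-1.3	0.8
fond	1.9	0.5
free	1.9	0.6
friend	2.1	0.5
friendly	2.2	0.5
frightened	-2.4	0.6
frustrated	-1.9	0.6
fun	2.3	0.5
funny	1.9	0.6
gentle	1.8	0.5
glad	2.0	0.5
gloomy	-1.6	0.6
good	1.9	0.5
grateful	2.4	0.5
great	2.5	0.5
grief	-2.9	0.6
guilty	-2.0	0.6
happiness	2.9	0.5
happy	2.7	0.5
hate	-2.7	0.6
hated	-2.7	0.6
haunted	-1.9	0.7
heartbroken	-3.0	0.6
heaven	2.8	0.7
hell	-2.9	0.7
helpless	-2.1	0.6
hide	-0.8	0.7
hiding	-0.9	0.7
hope	2.0	0.5
hopeful	2.2	0.5
hopeless	-2.6	0.6
horrible	-2.8	0.5
horror	-2.9	0.6
hug	2.1	0.5
hurt	-2.2	0.6
insecure	-1.6	0.6
inspired	2.3	0.5
joy	3.0	0.4
joyful	3.0	0.5
kill	-3.2	0.6
killed	-3.1	0.6
kind	2.2	0.5
kiss	2.3	0.6
laugh	2.2	0.5
laughed	2.2	0.5
laughing	2.3	0.5
lonely	-2.0	0.6
lost	-1.5	0.7
love	3.2	0.4
loved	3.0	0.5
lovely	2.8	0.5
loving	2.9	0.5
lucky	2.2	0.6
mad	-2.0	0.6
miserable	-2.7	0.5
miss	-1.0	0.7
missed	-1.1	0.7
monster	-2.0	0.8
murder	-3.4	0.6
nervous	-1.7	0.6
nice	1.8	0.5
nightmare	-2.8	0.6
pain	-2.5	0.5
painful	-2.5	0.5
panic	-2.5	0.6
paradise	3.1	0.5
peace	2.5	0.5
peaceful	2.4	0.5
perfect	2.7	0.5
play	1.5	0.6
played	1.4	0.6
playing	1.5	0.6
pleasant	2.1	0.5
pleased	2.1	0.5
pleasure	2.5	0.5
proud	2.3	0.5
rage	-2.7	0.6
relaxed	1.9	0.5
relief	1.9	0.6
relieved	2.0	0.5
sad	-2.1	0.5
sadness	-2.2	0.5
safe	1.8	0.5
satisfied	2.0	0.5
scared	-2.3	0.5
scary	-2.2	0.5
scream	-2.1	0.7
screamed	-2.2	0.7
screaming	-2.3	0.7
smile	2.1	0.5
smiled	2.1	0.5
smiling	2.2	0.5
sorrow	-2.6	0.5
sorry	-1.1	0.6
stress	-1.9	0.6
stressed	-2.0	0.6
struggle	-1.7	0.6
stuck	-1.3	0.7
suffering	-2.7	0.6
sunny	1.8	0.6
sweet	2.0	0.5
terrible	-2.7	0.5
terrified	-2.9	0.5
terror	-3.0	0.6
thankful	2.3	0.5
threat	-2.2	0.6
threatened	-2.3	0.6
thrilled	2.8	0.5
tired	-1.2	0.6
trapped	-2.2	0.6
trouble	-1.8	0.6
ugly	-2.1	0.6
uncomfortable	-1.5	0.5
unhappy	-2.2	0.5
upset	-1.9	0.5
victory	2.6	0.6
violent	-2.6	0.6
warm	1.7	0.5
weak	-1.4	0.6
welcome	1.9	0.5
win	2.4	0.6
won	2.5	0.6
wonderful	2.9	0.4
worried	-1.9	0.5
worry	-1.8	0.5
worse	-2.1	0.5
worst	-2.8	0.5
wrong	-1.6	0.6
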