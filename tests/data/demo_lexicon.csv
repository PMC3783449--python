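affect,happy
affect,glad
affect,sad
affect,love
affect,hate
affect,excit*
posemo,happy
posemo,glad
posemo,love
posemo,great
posemo,good
negemo,sad
negemo,hate
negemo,angry
negemo,ugh
social,friend*
social,family
social,party
social,we
social,you
cogproc,think*
cogproc,know
cogproc,because
cogproc,why
function,the
function,a
function,and
function,of
function,to
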