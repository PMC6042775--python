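%
1	posemo
2	negemo
3	social
4	cogproc
5	percept
6	body
%
pleasure	1
happ*	1
joy	1
sweet	1
delight*	1
love	1	3
sad	2
fear	2
angr*	2
gloom*	2
hate	2
friend*	3
family	3
talk*	3
companion	3
think*	4
because	4
reason*	4
consider	4
know	4
wonder	4
wonder*	1
see	5
hear*	5
look*	5
bright	5
loud	5
hand*	6
heart	6
blood	6
sleep*	6
face	6
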